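import numpy as np
import pandas as pd
import pytest

from famherit.pedigree import Pedigree, PedigreeMember, grm
from famherit.phenotypes import ReferenceTables
from famherit.simulate import SyntheticConfig, generate_dataset, generate_pedigree


@pytest.fixture(scope="session")
def trio_pedigree() -> Pedigree:
    """One maternal-line family: grandmother -> mother -> child."""
    return Pedigree(
        [
            PedigreeMember("GM", "F1", None, None, "female"),
            PedigreeMember("M", "F1", "GM", None, "female"),
            PedigreeMember("C", "F1", "M", None, "male"),
        ]
    )


@pytest.fixture(scope="session")
def trio_grm_expected() -> np.ndarray:
    return np.array([[1.0, 0.5, 0.25], [0.5, 1.0, 0.5], [0.25, 0.5, 1.0]])


@pytest.fixture(scope="session")
def cohort65():
    """A default synthetic cohort: 65 trios, study-condition parameters."""
    return generate_dataset(SyntheticConfig(seed=20240917))


@pytest.fixture(scope="session")
def cohort_grm(cohort65):
    return grm(cohort65.pedigree)


@pytest.fixture(scope="session")
def reference_tables() -> ReferenceTables:
    return ReferenceTables.from_yaml()


@pytest.fixture(scope="session")
def ped65():
    return generate_pedigree(65, seed=0)
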