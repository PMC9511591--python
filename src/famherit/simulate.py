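"""Synthetic three-generation family datasets with known genetic architecture.

The generator emulates the study conditions: 65 maternal-line trios
(grandmother, mother, child aged 4-10; 195 individuals), polygenic vascular
traits with configurable heritability, an age effect, generation-specific
trait locations matched loosely to the cohort's descriptive medians, and
per-measure missingness at the cohort's completion rates.  Fathers are
unobserved, so a non-founder's breeding value is
g = g_mother/2 + N(0, 3/4 * sigma_g2): the marginal variance stays sigma_g2
and Cov(g) = sigma_g2 * G for the maternal-line GRM.

All randomness flows from one seed through a fixed-order
``numpy.random.SeedSequence`` spawn, so a dataset is regenerable bit-exactly
from (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pedigree import Pedigree, PedigreeMember, grm
from .phenotypes import write_phenotypes

__all__ = [
    "TraitParams",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_pedigree",
    "sample_breeding_values",
    "generate_traits",
    "generate_dataset",
]

_GENS = ("grandparent", "parent", "child")


@dataclass(frozen=True)
class TraitParams:
    """Generative parameters for one trait.

    ``mean`` / ``sd`` are per-generation location and scale on the raw
    measurement scale; within a generation the trait is
    mean + sd * (beta_age * age_z + beta_sex * sex + g + e) with
    Var(g) = h2 and Var(e) = 1 - h2 on the latent scale (heritability is
    invariant to the affine rescaling).  ``missing`` is the per-generation
    missingness probability.
    """

    h2: float
    mean: tuple[float, float, float] = (0.0, 0.0, 0.0)  # grandparent, parent, child
    sd: tuple[float, float, float] = (1.0, 1.0, 1.0)
    beta_age: float = 0.0  # per pooled-z-scored-age unit, latent scale
    beta_sex: float = 0.0  # male minus female offset, latent scale
    missing: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"h2 must be in [0,1], got {self.h2}")
        if any(not 0.0 <= m <= 1.0 for m in self.missing):
            raise ValueError("missingness rates must be in [0,1]")
        if any(s <= 0 for s in self.sd):
            raise ValueError("trait sds must be positive")


def _default_traits() -> dict[str, TraitParams]:
    # Locations/scales track the cohort's descriptive medians and IQR/1.35;
    # missingness tracks the per-measure completion counts out of 65 per
    # generation.  Heritabilities default to mid-range values for the
    # structural traits and weak values for the pressure/stiffness traits.
    return {
        "brachial_sbp": TraitParams(
            h2=0.1, mean=(133, 117, 103), sd=(20, 13, 8),
            beta_age=0.55, beta_sex=0.1, missing=(0, 0, 3 / 65),
        ),
        "brachial_dbp": TraitParams(
            h2=0.1, mean=(80, 73, 63), sd=(12, 9, 7),
            beta_age=0.5, beta_sex=0.1, missing=(0, 0, 3 / 65),
        ),
        "central_sbp": TraitParams(
            h2=0.1, mean=(126, 106, 92), sd=(19, 12, 9),
            beta_age=0.55, beta_sex=0.1, missing=(0, 0, 3 / 65),
        ),
        "central_dbp": TraitParams(
            h2=0.1, mean=(81, 74, 64), sd=(12, 8, 6),
            beta_age=0.5, beta_sex=0.1, missing=(0, 0, 3 / 65),
        ),
        "pwv": TraitParams(
            h2=0.1, mean=(8.45, 6.50, 4.33), sd=(1.36, 0.65, 0.47),
            beta_age=0.6, beta_sex=0.0, missing=(8 / 65, 4 / 65, 9 / 65),
        ),
        "cimt_left": TraitParams(
            h2=0.35, mean=(0.66, 0.50, 0.44), sd=(0.13, 0.074, 0.067),
            beta_age=0.7, beta_sex=0.0, missing=(2 / 65, 2 / 65, 2 / 65),
        ),
        "lvmi_bsa": TraitParams(
            h2=0.30, mean=(91.4, 82.8, 56.4), sd=(27, 27, 16),
            beta_age=0.5, beta_sex=0.15, missing=(7 / 65, 2 / 65, 2 / 65),
        ),
    }


@dataclass
class SyntheticConfig:
    """Design of a synthetic cohort; defaults emulate the study conditions."""

    n_families: int = 65
    p_female_child: float = 36 / 65
    traits: dict[str, TraitParams] = field(default_factory=_default_traits)
    age_loc: tuple[float, float, float] = (56.0, 29.0, 7.0)
    age_scale: tuple[float, float, float] = (7.0, 1.5, 1.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not 0.0 <= self.p_female_child <= 1.0:
            raise ValueError("p_female_child must be in [0,1]")


@dataclass
class SyntheticDataset:
    """Phenotype table, pedigree and the ground truth that generated them."""

    phenotypes: pd.DataFrame
    pedigree: Pedigree
    truth: dict


def generate_pedigree(
    n_families: int,
    seed: int | np.random.SeedSequence | np.random.Generator | None = 0,
    p_female_child: float = 36 / 65,
) -> Pedigree:
    """Disjoint maternal-line trios: grandmother -> mother -> child.

    Grandmothers and mothers are female by design; the child's sex is
    Bernoulli(p_female_child).  Fathers are absent throughout.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    members: list[PedigreeMember] = []
    for k in range(n_families):
        fam = f"F{k:04d}"
        gm, mo, ch = f"{fam}_GM", f"{fam}_M", f"{fam}_C"
        child_sex = "female" if rng.random() < p_female_child else "male"
        members.append(PedigreeMember(gm, fam, None, None, "female"))
        members.append(PedigreeMember(mo, fam, gm, None, "female"))
        members.append(PedigreeMember(ch, fam, mo, None, child_sex))
    return Pedigree(members)


def sample_breeding_values(
    ped: Pedigree,
    sigma_g2: float,
    seed: int | np.random.SeedSequence | np.random.Generator | None = 0,
) -> np.ndarray:
    """Breeding values down the pedigree with Mendelian segregation noise.

    Founders draw g ~ N(0, sigma_g2); an individual with only the mother
    known draws g = g_mother/2 + N(0, 3/4 sigma_g2) (the unobserved father
    contributes an independent founder half), and with both parents known
    g = (g_m + g_f)/2 + N(0, sigma_g2/2).  The resulting covariance is
    sigma_g2 * G.
    """
    if sigma_g2 < 0:
        raise ValueError("sigma_g2 must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = np.zeros(len(ped))
    if sigma_g2 == 0:
        return g
    idx = {m.individual_id: i for i, m in enumerate(ped.members)}
    for i, m in enumerate(ped.members):
        mi = idx.get(m.mother_id) if m.mother_id else None
        fi = idx.get(m.father_id) if m.father_id else None
        if mi is None and fi is None:
            g[i] = rng.normal(scale=math.sqrt(sigma_g2))
        elif mi is not None and fi is not None:
            g[i] = 0.5 * (g[mi] + g[fi]) + rng.normal(scale=math.sqrt(0.5 * sigma_g2))
        else:
            known = g[mi if mi is not None else fi]
            g[i] = 0.5 * known + rng.normal(scale=math.sqrt(0.75 * sigma_g2))
    return g


def _covariates(ped: Pedigree, config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    gen_of = {"GM": "grandparent", "M": "parent", "C": "child"}
    rows = []
    for m in ped.members:
        gen = gen_of[m.individual_id.rsplit("_", 1)[1]]
        gi = _GENS.index(gen)
        if gen == "child":
            age = float(rng.uniform(4.0, 10.0))
            height = 85.0 + 5.4 * age + rng.normal(scale=5.0)
            weight = 8.0 + 2.2 * age + rng.normal(scale=3.0)
            waist = 0.45 * height + rng.normal(scale=4.0)
            muac = 13.0 + 0.7 * age + rng.normal(scale=1.5)
        else:
            age = float(np.clip(rng.normal(config.age_loc[gi], config.age_scale[gi]), 20, 95))
            height = rng.normal(157.5 if gen == "grandparent" else 159.5, 6.0)
            weight = np.clip(rng.normal(83.0 if gen == "grandparent" else 73.0, 16.0), 38, None)
            waist = 0.35 * weight + 60.0 + rng.normal(scale=6.0)
            muac = 0.2 * weight + 18.0 + rng.normal(scale=2.5)
        rows.append(
            dict(
                individual_id=m.individual_id,
                family_id=m.family_id,
                generation=gen,
                sex=m.sex,
                mother_id=m.mother_id,
                age=round(age, 1),
                height=round(float(height), 1),
                weight=round(float(weight), 1),
                waist=round(float(waist), 1),
                muac=round(float(muac), 1),
            )
        )
    return pd.DataFrame(rows)


def generate_traits(
    ped: Pedigree,
    breeding: dict[str, np.ndarray],
    config: SyntheticConfig,
    seed: int | np.random.SeedSequence | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Phenotype table for a pedigree given per-trait breeding values.

    Each trait is mean_gen + sd_gen * (beta_age * age_z + beta_sex * male +
    g + e) with e ~ N(0, 1 - h2) iid and age_z the pooled z-scored age;
    missingness is then applied independently per measure at the configured
    per-generation rates.  LVM is back-filled as LVMI x Mosteller BSA so the
    derived-phenotype consistency invariant holds on generated data.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = _covariates(ped, config, rng)
    n = len(df)
    gen_idx = df["generation"].map({g: i for i, g in enumerate(_GENS)}).to_numpy()
    age = df["age"].to_numpy(dtype=float)
    age_z = (age - age.mean()) / age.std(ddof=1)
    male = (df["sex"] == "male").to_numpy(dtype=float)

    for trait, tp in config.traits.items():
        g = breeding.get(trait)
        if g is None:
            raise ValueError(f"no breeding values supplied for trait {trait!r}")
        e = rng.normal(scale=math.sqrt(max(1.0 - tp.h2, 0.0)), size=n)
        latent = tp.beta_age * age_z + tp.beta_sex * male + g + e
        mean = np.asarray(tp.mean)[gen_idx]
        sd = np.asarray(tp.sd)[gen_idx]
        vals = mean + sd * latent
        miss = rng.random(n) < np.asarray(tp.missing)[gen_idx]
        df[trait] = np.where(miss, np.nan, vals)

    # derived/auxiliary measures for descriptive reporting
    if {"brachial_sbp", "brachial_dbp"} <= set(config.traits):
        df["pulse_pressure"] = df["brachial_sbp"] - df["brachial_dbp"]
        df["mean_arterial_pressure"] = df["brachial_dbp"] + df["pulse_pressure"] / 3.0
    df["resting_hr"] = np.round(
        np.where(gen_idx == 2, rng.normal(80, 9, n), rng.normal(67, 9, n)), 0
    )
    if "lvmi_bsa" in df.columns:
        bsa = np.sqrt(df["height"] * df["weight"] / 3600.0)
        df["lvm"] = df["lvmi_bsa"] * bsa
    adult = gen_idx < 2
    meds = rng.random(n) < np.where(gen_idx == 0, 0.62, 0.03)
    tobacco = rng.random(n) < np.where(gen_idx == 0, 0.28, 0.17)
    df["on_antihypertensives"] = np.where(adult, meds, None)
    df["tobacco_user"] = np.where(adult, tobacco, None)
    audit_c = rng.integers(0, 6, n).astype(float)
    audit_extra = rng.integers(0, 7, n).astype(float)
    df["audit_c"] = np.where(adult, audit_c, np.nan)
    df["audit_total"] = np.where(adult, audit_c + audit_extra, np.nan)
    return df


def generate_dataset(
    config: SyntheticConfig | None = None, out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Compose pedigree, breeding values and traits into a full dataset.

    With ``out_dir`` set, writes ``phenotypes.csv``, ``pedigree.fam`` and a
    ``truth.yaml`` sidecar holding the generative parameters and breeding
    values for recovery tests.
    """
    config = config or SyntheticConfig()
    root = np.random.SeedSequence(config.seed)
    ped_ss, bv_ss, trait_ss = root.spawn(3)
    ped = generate_pedigree(config.n_families, seed=ped_ss, p_female_child=config.p_female_child)
    bv_streams = bv_ss.spawn(len(config.traits))
    breeding = {
        trait: sample_breeding_values(ped, tp.h2, seed=ss)
        for (trait, tp), ss in zip(config.traits.items(), bv_streams)
    }
    phen = generate_traits(ped, breeding, config, seed=trait_ss)
    truth = {
        "seed": config.seed,
        "n_families": config.n_families,
        "traits": {t: asdict(tp) for t, tp in config.traits.items()},
        "breeding_values": {t: [float(v) for v in g] for t, g in breeding.items()},
    }
    ds = SyntheticDataset(phenotypes=phen, pedigree=ped, truth=truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_phenotypes(phen, out / "phenotypes.csv")
        from .pedigree import write_fam

        write_fam(ped, out / "pedigree.fam")
        (out / "truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=False))
    return ds
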