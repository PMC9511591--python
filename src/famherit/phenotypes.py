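"""Domain types and derived-phenotype rules for three-generation family data.

The study design is a maternal-line trio per family: grandmother, mother and
a child aged 4-10 years.  All adults are female; children are of either sex.
This module holds the per-individual record types, the clinical derivation
rules (blood-pressure averaging and status, BMI categories, hazardous alcohol
use, Devereux left-ventricular mass, body surface area, LVMI/LVH, waist-to-
height ratio) and the CSV reader/writer for the phenotype table.

Missing data propagate: every derivation raises :class:`MissingDataError` or
returns nothing rather than imputing.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from importlib import resources as _importlib_resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Generation",
    "Sex",
    "BmiCategory",
    "AdultBpStatus",
    "ChildBpStatus",
    "Individual",
    "PhenotypeRecord",
    "BPReadingTriplet",
    "ReferenceTables",
    "DomainError",
    "MissingDataError",
    "ReferenceTableError",
    "average_bp",
    "classify_bmi_adult",
    "classify_bmi_child",
    "classify_bp_adult",
    "classify_bp_child",
    "audit_hazardous",
    "devereux_lvm",
    "body_surface_area",
    "lvmi_and_lvh",
    "waist_to_height",
    "derive_phenotypes",
    "read_phenotypes",
    "write_phenotypes",
    "PHENOTYPE_COLUMNS",
]


class DomainError(ValueError):
    """An input lies outside the physical/clinical domain of an operation."""


class MissingDataError(ValueError):
    """A required measurement is absent; derived values are never imputed."""


class ReferenceTableError(KeyError):
    """A reference-table lookup does not cover the requested stratum."""


class Generation(str, enum.Enum):
    GRANDPARENT = "grandparent"
    PARENT = "parent"
    CHILD = "child"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class BmiCategory(str, enum.Enum):
    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESE = "obese"


class AdultBpStatus(str, enum.Enum):
    NORMAL = "normal"
    PREHYPERTENSION = "prehypertension"
    HYPERTENSION = "hypertension"


class ChildBpStatus(str, enum.Enum):
    NORMAL = "normal"
    ELEVATED = "elevated"
    HYPERTENSION = "hypertension"


@dataclass(frozen=True)
class Individual:
    """Identity, family links and anthropometry for one study participant.

    ``mother_id`` encodes the maternal line: a parent's mother is a
    grandparent of the same family and a child's mother is a parent of the
    same family.  Fathers are unobserved throughout.
    """

    individual_id: str
    family_id: str
    generation: Generation
    sex: Sex
    mother_id: str | None = None
    age: float | None = None
    height: float | None = None  # cm
    weight: float | None = None  # kg
    waist: float | None = None  # cm
    muac: float | None = None  # mid-upper arm circumference, cm

    def __post_init__(self) -> None:
        if self.age is not None and self.age <= 0:
            raise DomainError(f"age must be positive, got {self.age}")
        for name in ("height", "weight"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(f"{name} must be positive, got {v}")
        if self.generation in (Generation.GRANDPARENT, Generation.PARENT):
            if self.sex is not Sex.FEMALE:
                raise DomainError(
                    f"{self.individual_id}: {self.generation.value}s are female "
                    "in a maternal-line design"
                )


@dataclass(frozen=True)
class PhenotypeRecord:
    """Raw and derived vascular measures for one individual.

    All pressures in mm Hg, PWV in m/s, cIMT in mm, echo dimensions in cm,
    LVM in g, LVMI in g/m².  Any field may be missing (None): per-measure
    completion differs across the cohort.
    """

    individual_id: str
    brachial_sbp: float | None = None
    brachial_dbp: float | None = None
    central_sbp: float | None = None
    central_dbp: float | None = None
    pulse_pressure: float | None = None
    mean_arterial_pressure: float | None = None
    resting_hr: float | None = None
    pwv: float | None = None
    cimt_left: float | None = None
    ivsd: float | None = None
    lvidd: float | None = None
    pwd: float | None = None
    lvm: float | None = None
    lvmi_bsa: float | None = None
    on_antihypertensives: bool | None = None
    tobacco_user: bool | None = None
    audit_c: int | None = None
    audit_total: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "brachial_sbp",
            "brachial_dbp",
            "central_sbp",
            "central_dbp",
            "pulse_pressure",
            "mean_arterial_pressure",
        ):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(f"{name} must be positive when present, got {v}")


@dataclass(frozen=True)
class BPReadingTriplet:
    """Three sequential seated (SBP, DBP) readings in mm Hg."""

    readings: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.readings) != 3:
            raise MissingDataError(
                f"a BP triplet needs exactly three readings, got {len(self.readings)}"
            )


@dataclass
class ReferenceTables:
    """Replaceable child reference tables plus the child LVMI threshold.

    ``iotf_child_bmi_cutoffs`` maps ``(sex, age)`` to BMI cut-offs
    ``{"underweight": .., "overweight": .., "obese": ..}``;
    ``aap_child_bp_percentiles`` maps ``(sex, age, height_band)`` to
    ``{"p90": (sbp, dbp), "p95": (sbp, dbp)}`` where ``height_band`` is one of
    the bands listed in ``height_bands`` (upper bounds in cm, ascending).
    A value at or above a cut-off enters the higher category.
    """

    iotf_child_bmi_cutoffs: Mapping[tuple[str, int], Mapping[str, float]]
    aap_child_bp_percentiles: Mapping[tuple[str, int, int], Mapping[str, tuple[float, float]]]
    height_bands: Sequence[float]
    child_lvmi_p95: float = 109.4

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "ReferenceTables":
        """Load tables from a YAML resource (bundled synthetic fixture by default)."""
        if path is None:
            ref = _importlib_resources.files("famherit.resources").joinpath(
                "synthetic_reference_tables.yaml"
            )
            raw = yaml.safe_load(ref.read_text())
        else:
            raw = yaml.safe_load(Path(path).read_text())
        bmi = {
            (e["sex"], int(e["age"])): {
                "underweight": float(e["underweight"]),
                "overweight": float(e["overweight"]),
                "obese": float(e["obese"]),
            }
            for e in raw["iotf_child_bmi_cutoffs"]
        }
        bp = {
            (e["sex"], int(e["age"]), int(e["height_band"])): {
                "p90": (float(e["p90_sbp"]), float(e["p90_dbp"])),
                "p95": (float(e["p95_sbp"]), float(e["p95_dbp"])),
            }
            for e in raw["aap_child_bp_percentiles"]
        }
        return cls(
            iotf_child_bmi_cutoffs=bmi,
            aap_child_bp_percentiles=bp,
            height_bands=[float(b) for b in raw["height_bands"]],
            child_lvmi_p95=float(raw["child_lvmi_p95"]),
        )


# ---------------------------------------------------------------------------
# Derivation rules
# ---------------------------------------------------------------------------


def average_bp(triplet: BPReadingTriplet) -> tuple[float, float]:
    """Average the second and third of three BP readings; the first is discarded.

    The first reading absorbs the alerting response; analysis uses the mean of
    readings 2 and 3 per pressure component.
    """
    (_, _), (s2, d2), (s3, d3) = triplet.readings
    return ((s2 + s3) / 2.0, (d2 + d3) / 2.0)


def classify_bmi_adult(bmi: float) -> BmiCategory:
    """WHO adult BMI category: <18.5 / [18.5,25) / [25,30) / >=30 kg/m²."""
    if bmi <= 0 or not math.isfinite(bmi):
        raise DomainError(f"BMI must be positive and finite, got {bmi}")
    if bmi < 18.5:
        return BmiCategory.UNDERWEIGHT
    if bmi < 25.0:
        return BmiCategory.NORMAL
    if bmi < 30.0:
        return BmiCategory.OVERWEIGHT
    return BmiCategory.OBESE


def classify_bmi_child(
    sex: Sex | str, age: float, bmi: float, tables: ReferenceTables
) -> BmiCategory:
    """Child BMI category from age- and sex-specific cut-offs.

    Cut-offs are looked up at the nearest tabulated integer age (ties round
    down); a value at or above a cut-off enters the higher category.
    """
    if bmi <= 0:
        raise DomainError(f"BMI must be positive, got {bmi}")
    sex_key = sex.value if isinstance(sex, Sex) else str(sex)
    ages = sorted({a for (s, a) in tables.iotf_child_bmi_cutoffs if s == sex_key})
    if not ages:
        raise ReferenceTableError(f"no BMI cut-offs for sex={sex_key}")
    nearest = min(ages, key=lambda a: (abs(a - age), a))
    if abs(nearest - age) > 1.0:
        raise ReferenceTableError(
            f"BMI cut-offs do not cover age {age} for sex={sex_key} "
            f"(tabulated ages {ages[0]}..{ages[-1]})"
        )
    cuts = tables.iotf_child_bmi_cutoffs[(sex_key, nearest)]
    if bmi >= cuts["obese"]:
        return BmiCategory.OBESE
    if bmi >= cuts["overweight"]:
        return BmiCategory.OVERWEIGHT
    if bmi < cuts["underweight"]:
        return BmiCategory.UNDERWEIGHT
    return BmiCategory.NORMAL


def classify_bp_adult(
    sbp: float | None, dbp: float | None, on_meds: bool
) -> AdultBpStatus:
    """Adult BP status.

    Hypertension: SBP>=140 or DBP>=90 or currently on antihypertensive
    medication.  Prehypertension: SBP in [120,140) or DBP in [80,90) and not
    medicated.  Medication alone suffices for hypertension even when the
    pressures are missing.
    """
    if on_meds:
        return AdultBpStatus.HYPERTENSION
    if sbp is None or dbp is None:
        raise MissingDataError("BP status needs both pressures when unmedicated")
    if sbp >= 140 or dbp >= 90:
        return AdultBpStatus.HYPERTENSION
    if 120 <= sbp < 140 or 80 <= dbp < 90:
        return AdultBpStatus.PREHYPERTENSION
    return AdultBpStatus.NORMAL


def _height_band(height: float, bands: Sequence[float]) -> int:
    for i, ub in enumerate(bands):
        if height <= ub:
            return i
    return len(bands) - 1


def classify_bp_child(
    sex: Sex | str,
    age: float,
    height: float,
    sbp: float,
    dbp: float,
    tables: ReferenceTables,
) -> ChildBpStatus:
    """Child BP status from age-, sex- and height-adjusted percentile thresholds.

    At or above the 95th-percentile threshold (either component) is
    hypertension; at or above the 90th is elevated; below both is normal.
    """
    sex_key = sex.value if isinstance(sex, Sex) else str(sex)
    band = _height_band(height, tables.height_bands)
    ages = sorted({a for (s, a, b) in tables.aap_child_bp_percentiles if s == sex_key and b == band})
    if not ages:
        raise ReferenceTableError(f"no BP percentiles for sex={sex_key}, band={band}")
    nearest = min(ages, key=lambda a: (abs(a - age), a))
    if abs(nearest - age) > 1.0:
        raise ReferenceTableError(
            f"BP percentiles do not cover age {age} for sex={sex_key}"
        )
    thr = tables.aap_child_bp_percentiles[(sex_key, nearest, band)]
    p90_s, p90_d = thr["p90"]
    p95_s, p95_d = thr["p95"]
    if sbp >= p95_s or dbp >= p95_d:
        return ChildBpStatus.HYPERTENSION
    if sbp >= p90_s or dbp >= p90_d:
        return ChildBpStatus.ELEVATED
    return ChildBpStatus.NORMAL


def audit_hazardous(audit_c: int | None, audit_total: int | None) -> bool:
    """Hazardous/harmful alcohol use: AUDIT-C >= 3 and/or total AUDIT >= 8."""
    if audit_c is None and audit_total is None:
        raise MissingDataError("both AUDIT scores missing")
    return (audit_c is not None and audit_c >= 3) or (
        audit_total is not None and audit_total >= 8
    )


def devereux_lvm(ivsd: float, lvidd: float, pwd: float) -> float:
    """Left-ventricular mass (g) from M-mode echo dimensions (cm).

    ASE-cube Devereux-Reichek corrected formula:
    LVM = 0.8 * 1.04 * ((IVSd + LVIDd + PWd)^3 - LVIDd^3) + 0.6
    with the interventricular septal, LV internal-diastolic and posterior-wall
    dimensions in cm and myocardial density 1.04 g/mL.
    """
    for name, v in (("ivsd", ivsd), ("lvidd", lvidd), ("pwd", pwd)):
        if v is None or v <= 0:
            raise DomainError(f"{name} must be positive, got {v}")
    return 0.8 * 1.04 * ((ivsd + lvidd + pwd) ** 3 - lvidd**3) + 0.6


def body_surface_area(height: float, weight: float, method: str = "mosteller") -> float:
    """Body surface area in m² from height (cm) and weight (kg).

    Mosteller (default): sqrt(height*weight/3600).  Du Bois selectable because
    LVMI thresholds are sensitive to the BSA formula.
    """
    if height <= 0 or weight <= 0:
        raise DomainError(f"height and weight must be positive, got {height}, {weight}")
    if method == "mosteller":
        return math.sqrt(height * weight / 3600.0)
    if method == "dubois":
        return 0.007184 * height**0.725 * weight**0.425
    raise ValueError(f"unknown BSA method {method!r}")


def lvmi_and_lvh(
    lvm: float,
    bsa: float,
    generation: Generation | str,
    tables: ReferenceTables,
) -> tuple[float, bool]:
    """Index LVM to BSA and flag left-ventricular hypertrophy.

    Adults (all female here): LVH iff LVMI > 95 g/m².  Children: LVH iff LVMI
    exceeds the tabulated 95th-percentile threshold.  Both strict inequalities.
    """
    if lvm <= 0 or bsa <= 0:
        raise DomainError(f"lvm and bsa must be positive, got {lvm}, {bsa}")
    gen = generation if isinstance(generation, Generation) else Generation(generation)
    lvmi = lvm / bsa
    if gen is Generation.CHILD:
        return lvmi, lvmi > tables.child_lvmi_p95
    return lvmi, lvmi > 95.0


def waist_to_height(waist: float, height: float) -> float:
    """Waist circumference / height (both cm); unitless, scale-invariant."""
    if waist <= 0 or height <= 0:
        raise DomainError(f"waist and height must be positive, got {waist}, {height}")
    return waist / height


# ---------------------------------------------------------------------------
# Phenotype table I/O
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS: tuple[str, ...] = (
    "individual_id",
    "family_id",
    "generation",
    "sex",
    "mother_id",
    "age",
    "height",
    "weight",
    "waist",
    "muac",
    "brachial_sbp",
    "brachial_dbp",
    "central_sbp",
    "central_dbp",
    "pulse_pressure",
    "mean_arterial_pressure",
    "resting_hr",
    "pwv",
    "cimt_left",
    "ivsd",
    "lvidd",
    "pwd",
    "lvm",
    "lvmi_bsa",
    "on_antihypertensives",
    "tobacco_user",
    "audit_c",
    "audit_total",
)

_BOOL_COLUMNS = ("on_antihypertensives", "tobacco_user")


def derive_phenotypes(
    df: pd.DataFrame, tables: ReferenceTables | None = None, bsa_method: str = "mosteller"
) -> pd.DataFrame:
    """Append derived columns to a phenotype table.

    Adds bmi, bmi_category, waist_height_ratio, bp_status, hazardous_alcohol,
    bsa and, where echo dimensions are present, lvm_devereux / lvmi_bsa / lvh.
    Missing inputs yield missing outputs (no imputation).
    """
    tables = tables or ReferenceTables.from_yaml()
    out = df.copy()

    def per_row(fn):
        return out.apply(fn, axis=1)

    def _num(row, col):
        v = row.get(col)
        return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

    def f_bmi(row):
        h, w = _num(row, "height"), _num(row, "weight")
        return w / (h / 100.0) ** 2 if h and w else np.nan

    out["bmi"] = per_row(f_bmi)

    def f_bmi_cat(row):
        bmi = row["bmi"]
        if not np.isfinite(bmi):
            return None
        try:
            if row["generation"] == Generation.CHILD.value:
                return classify_bmi_child(row["sex"], float(row["age"]), bmi, tables).value
            return classify_bmi_adult(bmi).value
        except (ReferenceTableError, DomainError):
            return None

    out["bmi_category"] = per_row(f_bmi_cat)

    def f_whr(row):
        w, h = _num(row, "waist"), _num(row, "height")
        return waist_to_height(w, h) if w and h else np.nan

    out["waist_height_ratio"] = per_row(f_whr)

    def f_bp(row):
        sbp, dbp = _num(row, "brachial_sbp"), _num(row, "brachial_dbp")
        try:
            if row["generation"] == Generation.CHILD.value:
                h = _num(row, "height")
                if sbp is None or dbp is None or h is None:
                    return None
                return classify_bp_child(row["sex"], float(row["age"]), h, sbp, dbp, tables).value
            meds = row.get("on_antihypertensives")
            meds = bool(meds) if meds is not None and meds is not np.nan else False
            return classify_bp_adult(sbp, dbp, meds).value
        except (MissingDataError, ReferenceTableError):
            return None

    out["bp_status"] = per_row(f_bp)

    def f_alcohol(row):
        ac = row.get("audit_c")
        at = row.get("audit_total")
        ac = None if ac is None or (isinstance(ac, float) and math.isnan(ac)) else int(ac)
        at = None if at is None or (isinstance(at, float) and math.isnan(at)) else int(at)
        if ac is None and at is None:
            return None
        return audit_hazardous(ac, at)

    out["hazardous_alcohol"] = per_row(f_alcohol)

    def f_bsa(row):
        h, w = _num(row, "height"), _num(row, "weight")
        return body_surface_area(h, w, method=bsa_method) if h and w else np.nan

    out["bsa"] = per_row(f_bsa)

    def f_lvm(row):
        dims = (_num(row, "ivsd"), _num(row, "lvidd"), _num(row, "pwd"))
        return devereux_lvm(*dims) if all(dims) else np.nan

    out["lvm_devereux"] = per_row(f_lvm)

    def f_lvmi(row):
        lvm = _num(row, "lvm") or (
            row["lvm_devereux"] if np.isfinite(row["lvm_devereux"]) else None
        )
        if lvm and np.isfinite(row["bsa"]):
            return lvm / row["bsa"]
        return _num(row, "lvmi_bsa") or np.nan

    derived_lvmi = per_row(f_lvmi)
    if "lvmi_bsa" in out.columns:
        out["lvmi_bsa"] = out["lvmi_bsa"].where(out["lvmi_bsa"].notna(), derived_lvmi)
    else:
        out["lvmi_bsa"] = derived_lvmi

    def f_lvh(row):
        lvmi = row["lvmi_bsa"]
        if not np.isfinite(lvmi):
            return None
        if row["generation"] == Generation.CHILD.value:
            return bool(lvmi > tables.child_lvmi_p95)
        return bool(lvmi > 95.0)

    out["lvh"] = per_row(f_lvh)
    return out


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype CSV (one row per individual, empty cell = missing)."""
    df = pd.read_csv(path, dtype={"individual_id": str, "family_id": str, "mother_id": str})
    missing = [c for c in ("individual_id", "family_id", "generation", "sex") if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing required columns: {missing}")
    for col in _BOOL_COLUMNS:
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False, True: True, False: False})
    bad_gen = set(df["generation"].dropna()) - {g.value for g in Generation}
    if bad_gen:
        raise ValueError(f"unknown generation labels: {sorted(bad_gen)}")
    bad_sex = set(df["sex"].dropna()) - {s.value for s in Sex}
    if bad_sex:
        raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    """Write a phenotype table as CSV with empty cells for missing values."""
    cols = [c for c in PHENOTYPE_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df.loc[:, cols + extra].to_csv(path, index=False)
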