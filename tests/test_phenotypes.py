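"""Derived-phenotype rules: BP averaging and status, BMI, AUDIT, LVM/LVMI, BSA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from famherit.phenotypes import (
    AdultBpStatus,
    BmiCategory,
    BPReadingTriplet,
    ChildBpStatus,
    DomainError,
    Generation,
    MissingDataError,
    audit_hazardous,
    average_bp,
    body_surface_area,
    classify_bmi_adult,
    classify_bmi_child,
    classify_bp_adult,
    classify_bp_child,
    devereux_lvm,
    lvmi_and_lvh,
    read_phenotypes,
    waist_to_height,
    write_phenotypes,
)


@pytest.mark.parametrize(
    "readings, expected",
    [
        (((130, 80), (120, 74), (124, 78)), (122, 76)),
        (((110, 70), (110, 70), (110, 70)), (110, 70)),
        (((100, 60), (101, 61), (102, 63)), (101.5, 62)),
    ],
)
def test_bp_averaging_uses_second_and_third_readings(readings, expected):
    assert average_bp(BPReadingTriplet(readings)) == expected


def test_bp_triplet_requires_three_readings():
    with pytest.raises(MissingDataError):
        BPReadingTriplet(((120, 80), (118, 79)))


@pytest.mark.parametrize(
    "bmi, cat",
    [
        (18.4, BmiCategory.UNDERWEIGHT),
        (18.5, BmiCategory.NORMAL),
        (24.95, BmiCategory.NORMAL),
        (25.0, BmiCategory.OVERWEIGHT),
        (29.99, BmiCategory.OVERWEIGHT),
        (30.0, BmiCategory.OBESE),
    ],
)
def test_adult_bmi_boundaries(bmi, cat):
    assert classify_bmi_adult(bmi) == cat


def test_adult_bmi_rejects_nonpositive():
    with pytest.raises(DomainError):
        classify_bmi_adult(0.0)


@given(st.floats(min_value=5, max_value=80))
@settings(derandomize=True, max_examples=200, deadline=None)
def test_adult_bmi_total_and_monotone(bmi):
    """Classification is total on positive BMI and ordered in BMI."""
    order = [
        BmiCategory.UNDERWEIGHT,
        BmiCategory.NORMAL,
        BmiCategory.OVERWEIGHT,
        BmiCategory.OBESE,
    ]
    cat = classify_bmi_adult(bmi)
    assert cat in order
    assert order.index(classify_bmi_adult(bmi + 1.0)) >= order.index(cat)


def test_child_bmi_uses_table_cutoffs(reference_tables):
    low = reference_tables.iotf_child_bmi_cutoffs[("female", 7)]["underweight"] - 1
    assert classify_bmi_child("female", 7, low, reference_tables) == BmiCategory.UNDERWEIGHT
    ow = reference_tables.iotf_child_bmi_cutoffs[("female", 7)]["overweight"]
    assert classify_bmi_child("female", 7, ow, reference_tables) == BmiCategory.OVERWEIGHT
    with pytest.raises(KeyError):
        classify_bmi_child("female", 15, 18.0, reference_tables)


def test_child_bmi_fixture_cutoffs(reference_tables):
    """bmi between the overweight and obese cut-offs -> overweight."""
    cuts = reference_tables.iotf_child_bmi_cutoffs[("male", 8)]
    mid = (cuts["overweight"] + cuts["obese"]) / 2
    assert classify_bmi_child("male", 8, mid, reference_tables) == BmiCategory.OVERWEIGHT


@pytest.mark.parametrize(
    "sbp, dbp, meds, status",
    [
        (118, 76, False, AdultBpStatus.NORMAL),
        (135, 78, False, AdultBpStatus.PREHYPERTENSION),
        (118, 85, False, AdultBpStatus.PREHYPERTENSION),
        (140, 76, False, AdultBpStatus.HYPERTENSION),
        (118, 90, False, AdultBpStatus.HYPERTENSION),
        (118, 76, True, AdultBpStatus.HYPERTENSION),
        (119.9, 79.9, False, AdultBpStatus.NORMAL),
    ],
)
def test_adult_bp_status(sbp, dbp, meds, status):
    assert classify_bp_adult(sbp, dbp, meds) == status


def test_adult_bp_missing_pressure():
    with pytest.raises(MissingDataError):
        classify_bp_adult(None, 80, False)
    # medication alone suffices
    assert classify_bp_adult(None, None, True) == AdultBpStatus.HYPERTENSION


def test_child_bp_status_from_percentiles(reference_tables):
    thr = reference_tables.aap_child_bp_percentiles[("female", 7, 1)]
    p90s, p90d = thr["p90"]
    p95s, p95d = thr["p95"]
    kw = dict(sex="female", age=7, height=120, tables=reference_tables)
    assert classify_bp_child(sbp=p90s - 2, dbp=p90d - 2, **kw) == ChildBpStatus.NORMAL
    assert classify_bp_child(sbp=p90s + 1, dbp=p90d - 2, **kw) == ChildBpStatus.ELEVATED
    assert classify_bp_child(sbp=p95s, dbp=p90d - 2, **kw) == ChildBpStatus.HYPERTENSION


@pytest.mark.parametrize(
    "audit_c, total, expected",
    [(3, 5, True), (2, 8, True), (2, 7, False), (None, 9, True), (1, None, False)],
)
def test_hazardous_alcohol_rule(audit_c, total, expected):
    assert audit_hazardous(audit_c, total) is expected


def test_hazardous_alcohol_requires_a_score():
    with pytest.raises(MissingDataError):
        audit_hazardous(None, None)


def test_devereux_lvm_worked_example():
    # 0.8*1.04*((0.9+4.8+0.9)^3 - 4.8^3) + 0.6
    assert devereux_lvm(0.9, 4.8, 0.9) == pytest.approx(147.784128, abs=1e-6)


def test_devereux_rejects_nonpositive_dimension():
    with pytest.raises(DomainError):
        devereux_lvm(0.0, 4.8, 0.0)


@given(
    st.floats(min_value=0.4, max_value=2.0),
    st.floats(min_value=2.0, max_value=7.0),
    st.floats(min_value=0.4, max_value=2.0),
)
@settings(derandomize=True, max_examples=50, deadline=None)
def test_devereux_cubic_homogeneity(ivsd, lvidd, pwd):
    """Doubling all dimensions multiplies (LVM - 0.6) by 8."""
    small = devereux_lvm(ivsd, lvidd, pwd) - 0.6
    big = devereux_lvm(2 * ivsd, 2 * lvidd, 2 * pwd) - 0.6
    assert big == pytest.approx(8 * small, rel=1e-9)


def test_bsa_mosteller_worked_example():
    assert body_surface_area(160, 57.6) == pytest.approx(1.600, abs=1e-9)


def test_bsa_methods_and_monotonicity():
    base = body_surface_area(160, 60)
    assert body_surface_area(170, 60) > base
    assert body_surface_area(160, 70) > base
    assert body_surface_area(160, 60, method="dubois") == pytest.approx(
        0.007184 * 160**0.725 * 60**0.425
    )
    with pytest.raises(DomainError):
        body_surface_area(-1, 60)


def test_lvmi_and_lvh_thresholds(reference_tables):
    lvmi, lvh = lvmi_and_lvh(160.0, 1.6, Generation.PARENT, reference_tables)
    assert lvmi == pytest.approx(100.0)
    assert lvh  # adult threshold 95, strict
    assert not lvmi_and_lvh(95.0, 1.0, Generation.GRANDPARENT, reference_tables)[1]
    assert lvmi_and_lvh(95.1, 1.0, Generation.GRANDPARENT, reference_tables)[1]
    # child threshold is the tabulated 95th percentile (109.4 g/m^2)
    assert lvmi_and_lvh(110.0, 1.0, Generation.CHILD, reference_tables)[1]
    assert not lvmi_and_lvh(109.0, 1.0, Generation.CHILD, reference_tables)[1]


def test_lvmi_dimensional_round_trip(reference_tables):
    """LVM from echo dims, indexed by BSA, is consistent under unit scaling."""
    lvm = devereux_lvm(0.9, 4.8, 0.9)
    bsa = body_surface_area(160, 57.6)
    lvmi, _ = lvmi_and_lvh(lvm, bsa, Generation.PARENT, reference_tables)
    assert lvmi == pytest.approx(lvm / bsa)


@given(st.floats(min_value=0.1, max_value=10))
@settings(derandomize=True, max_examples=50, deadline=None)
def test_waist_to_height_scale_invariance(k):
    assert waist_to_height(54.8 * k, 122.5 * k) == pytest.approx(54.8 / 122.5)


def test_waist_to_height_values():
    assert waist_to_height(80, 160) == pytest.approx(0.5)
    assert waist_to_height(104.4, 157.3) == pytest.approx(0.6637, abs=5e-4)
    with pytest.raises(DomainError):
        waist_to_height(80, 0)


def test_phenotype_csv_round_trip(tmp_path, cohort65):
    path = tmp_path / "phen.csv"
    write_phenotypes(cohort65.phenotypes, path)
    back = read_phenotypes(path)
    for col in ("pwv", "cimt_left", "lvmi_bsa", "age"):
        a = cohort65.phenotypes[col].astype(float).to_numpy()
        b = back[col].astype(float).to_numpy()
        assert np.array_equal(np.isnan(a), np.isnan(b))
        assert np.allclose(a[~np.isnan(a)], b[~np.isnan(b)])


def test_derive_phenotypes_adds_consistent_columns(cohort65, reference_tables):
    from famherit.phenotypes import derive_phenotypes

    out = derive_phenotypes(cohort65.phenotypes, reference_tables)
    for col in ("bmi", "bmi_category", "waist_height_ratio", "bp_status", "bsa", "lvh"):
        assert col in out.columns
    adults = out[out["generation"] != "child"]
    # bmi consistent with height/weight where both present
    row = adults.dropna(subset=["height", "weight"]).iloc[0]
    assert row["bmi"] == pytest.approx(row["weight"] / (row["height"] / 100) ** 2)
    # adult LVH agrees with the 95 g/m^2 rule wherever LVMI is present
    got = adults.dropna(subset=["lvmi_bsa"])
    assert all((r["lvmi_bsa"] > 95.0) == bool(r["lvh"]) for _, r in got.iterrows())
    # medicated adults are hypertensive regardless of pressures
    meds = adults[adults["on_antihypertensives"] == True]  # noqa: E712
    assert (meds["bp_status"] == "hypertension").all()
    # children without reference coverage would raise; ages 4-10 are covered
    kids = out[out["generation"] == "child"].dropna(subset=["bmi"])
    assert kids["bmi_category"].notna().all()
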