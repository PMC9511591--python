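"""Random family method: slope fitting, restricted resampling, empirical p."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from famherit.stage1 import (
    FitError,
    GenerationPair,
    InsufficientDataError,
    RandomFamilyTest,
    TraitSpec,
    _null_taus_fwl,
    _sample_derangements,
    default_trait_specs,
    empirical_p,
    extract_pairs,
    fit_tau,
    kde_tau,
    resample_null,
    run_stage1,
)


def _pairs(z, y, **covs):
    return pd.DataFrame({"z": z, "y": y, **covs})


def test_exact_fit_identity():
    z = np.array([1.0, 2.0, 3.0, 4.0])
    tau, _ = fit_tau(_pairs(z, 2 * z))
    assert tau == pytest.approx(2.0)


def test_constant_exposure_raises():
    with pytest.raises(FitError, match="constant"):
        fit_tau(_pairs(np.ones(5), np.arange(5.0)))


def test_constant_covariate_raises_naming_column():
    rng = np.random.default_rng(0)
    with pytest.raises(FitError, match="age"):
        fit_tau(
            _pairs(rng.normal(size=6), rng.normal(size=6), age=np.full(6, 30.0)),
            covariates=["age"],
        )


def test_fit_tau_matches_normal_equations_oracle():
    """n=6 fixture: tau agrees with an explicit (X'X)^-1 X'y solve."""
    z = np.array([1.2, -0.3, 0.8, 2.1, -1.5, 0.4])
    age = np.array([34.0, 29.0, 41.0, 52.0, 38.0, 45.0])
    y = np.array([0.7, -0.1, 0.9, 1.8, -0.9, 0.3])
    tau, coef = fit_tau(_pairs(z, y, age=age), covariates=["age"])
    X = np.column_stack([np.ones(6), age, z])
    oracle = np.linalg.solve(X.T @ X, X.T @ y)
    assert coef == pytest.approx(oracle)
    assert tau == pytest.approx(oracle[-1])


def test_derangements_have_no_fixed_points():
    rng = np.random.default_rng(7)
    perms = _sample_derangements(rng, 12, 200)
    assert perms.shape == (200, 12)
    assert not np.any(perms == np.arange(12))
    for p in perms[:20]:
        assert sorted(p) == list(range(12))


def test_derangement_needs_three_pairs():
    with pytest.raises(InsufficientDataError):
        _sample_derangements(np.random.default_rng(0), 2, 5)


def test_fwl_null_slopes_equal_full_refit():
    """The projection fast path is algebraically the per-permutation OLS refit."""
    rng = np.random.default_rng(5)
    n = 20
    z = rng.normal(size=n)
    age = rng.normal(50, 8, size=n)
    y = 0.4 * z + 0.02 * age + rng.normal(size=n)
    A = np.column_stack([np.ones(n), age])
    perms = _sample_derangements(rng, n, 25)
    fast = _null_taus_fwl(z, y, A, perms)
    for k, p in enumerate(perms):
        X = np.column_stack([A, z[p]])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert fast[k] == pytest.approx(coef[-1], rel=1e-9, abs=1e-12)


def test_resample_null_deterministic_and_counts():
    rng = np.random.default_rng(1)
    pairs = _pairs(rng.normal(size=30), rng.normal(size=30))
    a = resample_null(pairs, n_resamples=500, seed=42)
    b = resample_null(pairs, n_resamples=500, seed=42)
    assert a.shape == (500,)
    assert np.array_equal(a, b)
    c = resample_null(pairs, n_resamples=500, seed=43)
    assert not np.array_equal(a, c)


@pytest.mark.parametrize(
    "c, n",
    [(83, 5000), (3123, 5000), (213, 5000), (102, 5000)],
)
def test_empirical_p_is_exact_ratio(c, n):
    rng = np.random.default_rng(c)
    # construct a null with exactly c exceedances of |tau_obs| = 1
    null = np.concatenate([rng.uniform(1.0, 2.0, c), rng.uniform(0.0, 0.999, n - c)])
    rng.shuffle(null)
    cc, nn, p = empirical_p(1.0, null)
    assert (cc, nn) == (c, n)
    assert p == c / n


def test_empirical_p_edge_cases():
    assert empirical_p(5.0, np.array([1.0, -2.0, 3.0]))[2] == 0.0
    # ties count as exceedances
    assert empirical_p(1.0, np.array([1.0, -1.0, 1.0]))[2] == 1.0


@given(
    st.floats(min_value=0.1, max_value=50),
    st.floats(min_value=-10, max_value=10),
)
@settings(derandomize=True, max_examples=25, deadline=None)
def test_affine_rescaling_leaves_p_invariant(scale, shift):
    """Changing measurement units of z and y does not move (c, n, p)."""
    rng = np.random.default_rng(11)
    z = rng.normal(size=25)
    age = rng.normal(40, 5, size=25)
    y = 0.3 * z + rng.normal(size=25)
    base = _pairs(z, y, age=age)
    scaled = _pairs(scale * z + shift, scale * y + shift, age=age)
    t0, _ = fit_tau(base, covariates=["age"])
    t1, _ = fit_tau(scaled, covariates=["age"])
    n0 = resample_null(base, covariates=["age"], n_resamples=300, seed=9)
    n1 = resample_null(scaled, covariates=["age"], n_resamples=300, seed=9)
    assert empirical_p(t0, n0) == empirical_p(t1, n1)


def test_extract_pairs_all_three_pairings(cohort65):
    phen = cohort65.phenotypes
    for gp in GenerationPair:
        spec = TraitSpec("cimt_left", ("age", "height", "weight", "sex"), gp)
        pairs = extract_pairs(phen, spec)
        assert 50 <= len(pairs) <= 65
        assert pairs[["z", "y"]].notna().all().all()


def test_extract_pairs_pairwise_completeness(cohort65):
    """A family missing the child trait drops from child rows only."""
    phen = cohort65.phenotypes.copy()
    spec_gc = TraitSpec("cimt_left", ("age", "height", "weight", "sex"), GenerationPair.GC_ON_P)
    spec_p = TraitSpec("cimt_left", ("age", "height", "weight", "sex"), GenerationPair.P_ON_GP)
    victim = extract_pairs(phen, spec_gc)["offspring_id"].iloc[0]
    before_gc = len(extract_pairs(phen, spec_gc))
    before_p = len(extract_pairs(phen, spec_p))
    phen.loc[phen["individual_id"] == victim, "cimt_left"] = np.nan
    assert len(extract_pairs(phen, spec_gc)) == before_gc - 1
    assert len(extract_pairs(phen, spec_p)) == before_p


def test_extract_pairs_insufficient_data(cohort65):
    phen = cohort65.phenotypes.copy()
    phen.loc[phen["generation"] == "child", "pwv"] = np.nan
    spec = TraitSpec("pwv", ("age", "height", "weight", "sex"), GenerationPair.GC_ON_P)
    with pytest.raises(InsufficientDataError):
        extract_pairs(phen, spec)


def test_run_stage1_produces_21_rows(cohort65):
    results = run_stage1(cohort65.phenotypes, n_resamples=200, seed=5)
    assert len(results) == 21
    assert {r.spec.trait_name for r in results} == {
        "brachial_sbp", "brachial_dbp", "central_sbp", "central_dbp",
        "pwv", "cimt_left", "lvmi_bsa",
    }
    for r in results:
        assert not r.insufficient
        # p = c/n holds exactly, re-derived from the stored null draws
        c, n, p = empirical_p(r.tau_obs, r.null_taus)
        assert (r.c, r.n, r.p) == (c, n, p)
        assert r.significant == (r.p < 0.05)
        # offspring all-female rows must have dropped the sex covariate
        if r.spec.generation_pair is GenerationPair.P_ON_GP and "sex" in r.spec.covariates:
            assert "sex" in r.dropped_covariates


def test_run_stage1_empty_dataset_flags_all_rows(cohort65):
    empty = cohort65.phenotypes.iloc[0:0]
    results = run_stage1(empty, n_resamples=50, seed=0)
    assert len(results) == 21
    assert all(r.insufficient for r in results)


def test_estimator_api_matches_functions():
    rng = np.random.default_rng(2)
    n = 40
    z = rng.normal(size=n)
    age = rng.normal(size=n)
    y = 0.5 * z + 0.3 * age + rng.normal(size=n)
    est = RandomFamilyTest(n_resamples=400, random_state=17).fit(
        np.column_stack([z, age]), y
    )
    pairs = _pairs(z, y, age=age)
    tau, _ = fit_tau(pairs, covariates=["age"])
    assert est.tau_ == pytest.approx(tau)
    assert est.p_value_ == est.c_ / est.n_
    assert est.null_taus_.shape == (400,)
    # sklearn param plumbing
    assert est.get_params()["n_resamples"] == 400
    assert type(est)(**est.get_params()).get_params() == est.get_params()


def test_power_increases_with_transmission_strength():
    """Median p over replicates decreases as the parent->offspring effect grows."""
    rng = np.random.default_rng(31)
    med_p = []
    for effect in (0.0, 0.3, 0.6):
        ps = []
        for _ in range(40):
            z = rng.normal(size=65)
            y = effect * z + rng.normal(size=65)
            pairs = _pairs(z, y)
            tau, _ = fit_tau(pairs)
            null = resample_null(pairs, n_resamples=200, seed=rng.integers(2**31))
            ps.append(empirical_p(tau, null)[2])
        med_p.append(np.median(ps))
    assert med_p[2] < med_p[1] < med_p[0]


def test_kde_density_normalises_and_matches_normal():
    rng = np.random.default_rng(8)
    null = rng.standard_normal(4000)
    grid, dens, obs = kde_tau(null, tau_obs=0.5)
    assert obs == 0.5
    assert np.all(dens >= 0)
    assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)
    at0 = dens[np.argmin(np.abs(grid))]
    assert at0 == pytest.approx(0.3989, abs=0.03)


def test_kde_degenerate_null_raises():
    with pytest.raises(ValueError):
        kde_tau(np.ones(10), 0.0)


def test_default_registry_covers_21_specs():
    specs = default_trait_specs()
    assert len(specs) == 21
    lvmi = [s for s in specs if s.trait_name == "lvmi_bsa"]
    assert all(s.covariates == ("age", "sex") for s in lvmi)
    with pytest.raises(ValueError, match="covariates"):
        TraitSpec("lvmi_bsa", ("age", "height", "weight", "sex"), GenerationPair.GC_ON_P)
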