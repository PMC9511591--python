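"""Stage 1: the random family method.

For each vascular trait and each generation pairing (grandparent->grandchild,
parent->grandchild in the sense of mother->child, grandparent->parent), the
offspring trait is regressed on the parental trait with covariate adjustment,
and the observed slope tau is referred to a null distribution built by
restricted resampling: the parental exposure vector is reassigned to offspring
by a random derangement (no offspring keeps its own biological parent),
yielding "random families".  The empirical probability is p = c/n with
c = #{|T| >= |T(obs)|} over n resampled slopes — ties count, no +1 smoothing,
so p = 0 is possible.

The resampling test is exposed both as functions mirroring the analysis steps
and as the :class:`RandomFamilyTest` estimator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "GenerationPair",
    "TraitSpec",
    "Stage1Result",
    "InsufficientDataError",
    "FitError",
    "TRAIT_REGISTRY",
    "default_trait_specs",
    "extract_pairs",
    "fit_tau",
    "resample_null",
    "empirical_p",
    "run_stage1",
    "kde_tau",
    "plot_kde",
    "write_stage1_tsv",
    "RandomFamilyTest",
]


class InsufficientDataError(ValueError):
    """Too few complete biological pairs to run the analysis."""


class FitError(ValueError):
    """The regression design is rank-deficient (e.g. a constant column)."""


class GenerationPair(str, enum.Enum):
    GC_ON_GP = "GC_on_GP"  # grandchild outcome, grandparent exposure
    GC_ON_P = "GC_on_P"  # grandchild outcome, parent (mother) exposure
    P_ON_GP = "P_on_GP"  # parent outcome, grandparent exposure


#: Covariate rules per trait: pressures, PWV and cIMT adjust for age, height,
#: weight and sex; LVMI adjusts for age and sex only, being already indexed
#: to body surface area.  Order matches the reporting layout.
TRAIT_REGISTRY: dict[str, tuple[str, ...]] = {
    "brachial_sbp": ("age", "height", "weight", "sex"),
    "brachial_dbp": ("age", "height", "weight", "sex"),
    "central_sbp": ("age", "height", "weight", "sex"),
    "central_dbp": ("age", "height", "weight", "sex"),
    "pwv": ("age", "height", "weight", "sex"),
    "cimt_left": ("age", "height", "weight", "sex"),
    "lvmi_bsa": ("age", "sex"),
}

_PAIR_ROLES: dict[GenerationPair, tuple[str, str]] = {
    # (outcome generation, exposure generation)
    GenerationPair.GC_ON_GP: ("child", "grandparent"),
    GenerationPair.GC_ON_P: ("child", "parent"),
    GenerationPair.P_ON_GP: ("parent", "grandparent"),
}


@dataclass(frozen=True)
class TraitSpec:
    """One exposure->outcome pairing of a trait with its covariate set."""

    trait_name: str
    covariates: tuple[str, ...]
    generation_pair: GenerationPair

    def __post_init__(self) -> None:
        if self.trait_name in TRAIT_REGISTRY:
            expected = TRAIT_REGISTRY[self.trait_name]
            if tuple(self.covariates) != expected:
                raise ValueError(
                    f"covariates for {self.trait_name} must be {expected}, "
                    f"got {tuple(self.covariates)}"
                )


def default_trait_specs() -> list[TraitSpec]:
    """The 21 trait x generation-pairing specs of the standard analysis."""
    return [
        TraitSpec(trait, TRAIT_REGISTRY[trait], pair)
        for trait in TRAIT_REGISTRY
        for pair in (GenerationPair.GC_ON_GP, GenerationPair.GC_ON_P, GenerationPair.P_ON_GP)
    ]


@dataclass
class Stage1Result:
    """Observed slope, resampling null and empirical p for one spec."""

    spec: TraitSpec
    tau_obs: float | None = None
    beta: np.ndarray | None = None
    n_pairs: int = 0
    null_taus: np.ndarray | None = None
    c: int | None = None
    n: int | None = None
    p: float | None = None
    dropped_covariates: tuple[str, ...] = ()
    insufficient: bool = False
    message: str = ""

    @property
    def significant(self) -> bool | None:
        return None if self.p is None else self.p < 0.05


# ---------------------------------------------------------------------------
# Pair extraction
# ---------------------------------------------------------------------------


def extract_pairs(
    dataset: pd.DataFrame,
    spec: TraitSpec,
    include_parental_covariates: bool = False,
) -> pd.DataFrame:
    """Build the pairwise-complete (z, y, covariates) table for one spec.

    One row per biological pair in which both trait values and every required
    covariate are present; families lacking the pair for this trait are simply
    dropped (the method needs only one valid biological pair per family, so
    completion is assessed per pairing, not per family).  Covariates are the
    offspring's by default; ``include_parental_covariates`` adds the exposure
    side's as ``z_<name>`` columns.

    Raises :class:`InsufficientDataError` below 3 complete pairs.
    """
    out_gen, exp_gen = _PAIR_ROLES[spec.generation_pair]
    needed = [spec.trait_name, *spec.covariates]
    absent = [c for c in needed if c not in dataset.columns]
    if absent:
        raise InsufficientDataError(
            f"{spec.trait_name} {spec.generation_pair.value}: "
            f"columns absent from dataset: {absent}"
        )
    by_id = dataset.set_index("individual_id", drop=False)
    mother_of = dataset.set_index("individual_id")["mother_id"].to_dict()

    def ancestor(iid: str, steps: int) -> str | None:
        cur: str | None = iid
        for _ in range(steps):
            if cur is None:
                return None
            cur = mother_of.get(cur)
            if cur is None or (isinstance(cur, float) and np.isnan(cur)):
                return None
        return cur

    steps = 2 if spec.generation_pair is GenerationPair.GC_ON_GP else 1
    rows = []
    offspring = dataset[dataset["generation"] == out_gen]
    for r in offspring.itertuples(index=False):
        exp_id = ancestor(r.individual_id, steps)
        if exp_id is None or exp_id not in by_id.index:
            continue
        exp_row = by_id.loc[exp_id]
        if exp_row["generation"] != exp_gen:
            continue
        rec: dict[str, object] = {
            "family_id": r.family_id,
            "offspring_id": r.individual_id,
            "exposure_id": exp_id,
            "z": exp_row[spec.trait_name],
            "y": getattr(r, spec.trait_name),
        }
        for cov in spec.covariates:
            rec[cov] = getattr(r, cov)
            if include_parental_covariates:
                rec[f"z_{cov}"] = exp_row[cov]
        rows.append(rec)

    pairs = pd.DataFrame(rows)
    if not pairs.empty:
        if "sex" in pairs.columns:
            pairs["sex"] = pairs["sex"].map({"female": 0.0, "male": 1.0, 0.0: 0.0, 1.0: 1.0})
        if "z_sex" in pairs.columns:
            pairs["z_sex"] = pairs["z_sex"].map({"female": 0.0, "male": 1.0, 0.0: 0.0, 1.0: 1.0})
        pairs = pairs.dropna().reset_index(drop=True)
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"{spec.trait_name} {spec.generation_pair.value}: "
            f"{len(pairs)} complete pairs (need >= 3)"
        )
    return pairs


# ---------------------------------------------------------------------------
# OLS slope and restricted resampling
# ---------------------------------------------------------------------------


def _design(pairs: pd.DataFrame, covariates: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    z = pairs["z"].to_numpy(dtype=float)
    y = pairs["y"].to_numpy(dtype=float)
    A = np.column_stack(
        [np.ones(len(pairs))] + [pairs[c].to_numpy(dtype=float) for c in covariates]
    )
    return z, y, A


def _check_full_rank(A: np.ndarray, names: Sequence[str], z: np.ndarray) -> None:
    if np.ptp(z) == 0:
        raise FitError("exposure column 'z' is constant")
    for j, name in enumerate(names, start=1):
        if np.ptp(A[:, j]) == 0:
            raise FitError(f"covariate column {name!r} is constant")
    full = np.column_stack([A, z])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise FitError("design matrix is rank deficient")


def fit_tau(
    pairs: pd.DataFrame, spec: TraitSpec | None = None, covariates: Sequence[str] | None = None
) -> tuple[float, np.ndarray]:
    """OLS fit of y = b0 + tau*z + beta'X; returns (tau, [b0, beta..., tau]).

    Raises :class:`FitError` on a constant exposure or covariate or a
    rank-deficient design, naming the offending column.
    """
    covs = list(covariates if covariates is not None else (spec.covariates if spec else []))
    covs = [c for c in covs if c in pairs.columns]
    z, y, A = _design(pairs, covs)
    _check_full_rank(A, covs, z)
    X = np.column_stack([A, z])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(coef[-1]), coef


def _null_taus_fwl(
    z: np.ndarray, y: np.ndarray, A: np.ndarray, perms: np.ndarray
) -> np.ndarray:
    """Slopes of permuted exposures via Frisch-Waugh-Lovell.

    With M the residual-maker of the covariate design A (which stays attached
    to the offspring rows), the OLS coefficient of the permuted exposure is
    (Mz_pi)'y / (Mz_pi)'(Mz_pi) — algebraically identical to refitting the
    full regression for every permutation.
    """
    Q, _ = np.linalg.qr(A)
    Zp = z[perms.T]  # (n_pairs, n_perms)
    MZ = Zp - Q @ (Q.T @ Zp)
    My = y - Q @ (Q.T @ y)
    num = MZ.T @ My
    den = np.einsum("ij,ij->j", MZ, MZ)
    return num / den


def _sample_derangements(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k uniformly random derangements of range(n) by rejection sampling."""
    if n < 3:
        raise InsufficientDataError(
            f"derangement resampling needs >= 3 pairs, got {n}"
        )
    out = np.empty((k, n), dtype=np.intp)
    base = np.arange(n)
    filled = 0
    while filled < k:
        batch = max(k - filled, 16)
        cand = np.argsort(rng.random((batch, n)), axis=1)
        ok = ~np.any(cand == base, axis=1)
        good = cand[ok]
        take = min(len(good), k - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return out


def resample_null(
    pairs: pd.DataFrame,
    spec: TraitSpec | None = None,
    n_resamples: int = 5000,
    seed: int | np.random.SeedSequence | None = 0,
    covariates: Sequence[str] | None = None,
    permutation: Literal["derangement", "free"] = "derangement",
) -> np.ndarray:
    """Null slope distribution from restricted resampling of the exposure.

    Each resample reassigns the parental exposure vector to offspring by a
    uniformly random derangement (``permutation="free"`` lifts the no-fixed-
    point restriction, for sensitivity analysis) and refits tau with the same
    covariate specification.  Fully reproducible from ``seed``.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    covs = list(covariates if covariates is not None else (spec.covariates if spec else []))
    covs = [c for c in covs if c in pairs.columns]
    z, y, A = _design(pairs, covs)
    _check_full_rank(A, covs, z)
    rng = np.random.default_rng(seed)
    if permutation == "derangement":
        perms = _sample_derangements(rng, len(z), n_resamples)
    elif permutation == "free":
        perms = np.argsort(rng.random((n_resamples, len(z))), axis=1)
    else:
        raise ValueError(f"unknown permutation mode {permutation!r}")
    return _null_taus_fwl(z, y, A, perms)


def empirical_p(tau_obs: float, null_taus: np.ndarray) -> tuple[int, int, float]:
    """(c, n, p) with c = #{|T| >= |T(obs)|}, p = c/n; ties count, no smoothing."""
    null_taus = np.asarray(null_taus, dtype=float)
    if null_taus.size == 0:
        raise ValueError("null_taus is empty")
    c = int(np.count_nonzero(np.abs(null_taus) >= abs(tau_obs)))
    n = int(null_taus.size)
    return c, n, c / n


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


class RandomFamilyTest(BaseEstimator):
    """Randomisation-inference test for a covariate-adjusted regression slope.

    Fits y = b0 + tau*z + beta'X by OLS and refers tau to the distribution of
    slopes obtained when the exposure z is reassigned to observations by
    random derangements (restricted resampling: no observation keeps its own
    exposure).  The empirical p-value is c/n with c the number of null slopes
    at least as large in magnitude as the observed one.

    Parameters
    ----------
    n_resamples : number of resampled "random family" sets (default 5000).
    permutation : "derangement" (restricted, default) or "free".
    random_state : seed for the resampling stream.

    Attributes (after ``fit(X, y)`` where column 0 of X is the exposure)
    ----------
    tau_ : observed slope on the exposure.
    beta_ : full coefficient vector [intercept, covariates..., tau].
    null_taus_ : the n_resamples resampled slopes.
    c_, n_, p_value_ : exceedance count, resample count, empirical p.
    n_pairs_ : number of complete observations used.
    """

    def __init__(
        self,
        n_resamples: int = 5000,
        permutation: Literal["derangement", "free"] = "derangement",
        random_state: int | None = 0,
    ) -> None:
        self.n_resamples = n_resamples
        self.permutation = permutation
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with rows matching y")
        if X.shape[0] < 3:
            raise InsufficientDataError("need >= 3 observations")
        names = [f"x{j}" for j in range(1, X.shape[1])]
        pairs = pd.DataFrame({"z": X[:, 0], "y": y, **{n: X[:, j + 1] for j, n in enumerate(names)}})
        self.tau_, self.beta_ = fit_tau(pairs, covariates=names)
        self.null_taus_ = resample_null(
            pairs,
            covariates=names,
            n_resamples=self.n_resamples,
            seed=self.random_state,
            permutation=self.permutation,
        )
        self.c_, self.n_, self.p_value_ = empirical_p(self.tau_, self.null_taus_)
        self.n_pairs_ = int(len(pairs))
        return self

    def score(self, X=None, y=None) -> float:
        """Return the observed slope (for model-selection plumbing)."""
        check_is_fitted(self, "tau_")
        return self.tau_


# ---------------------------------------------------------------------------
# Whole-table run, KDE diagnostics and reporting
# ---------------------------------------------------------------------------


def run_stage1(
    dataset: pd.DataFrame,
    specs: Iterable[TraitSpec] | None = None,
    n_resamples: int = 5000,
    seed: int | np.random.SeedSequence = 0,
    keep_null: bool = True,
    permutation: Literal["derangement", "free"] = "derangement",
) -> list[Stage1Result]:
    """Run the random family analysis for every spec (21 rows by default).

    Covariates constant within a pair table (e.g. sex when the offspring
    generation is all-female by design) are dropped for that row and recorded
    in ``dropped_covariates``.  Rows with insufficient data are flagged, not
    fatal.  Per-row seeds are spawned from the master seed, so each row is
    reproducible independently of the others.
    """
    specs = list(specs) if specs is not None else default_trait_specs()
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = root.spawn(len(specs))
    results: list[Stage1Result] = []
    for spec, ss in zip(specs, child_seeds):
        res = Stage1Result(spec=spec)
        try:
            pairs = extract_pairs(dataset, spec)
            covs = [c for c in spec.covariates if pairs[c].nunique() > 1]
            res.dropped_covariates = tuple(c for c in spec.covariates if c not in covs)
            res.tau_obs, res.beta = fit_tau(pairs, covariates=covs)
            res.n_pairs = len(pairs)
            null = resample_null(
                pairs,
                covariates=covs,
                n_resamples=n_resamples,
                seed=ss,
                permutation=permutation,
            )
            res.c, res.n, res.p = empirical_p(res.tau_obs, null)
            if keep_null:
                res.null_taus = null
        except (InsufficientDataError, FitError) as e:
            res.insufficient = True
            res.message = str(e)
        results.append(res)
    return results


def adjust_pvalues(results: list[Stage1Result], method: str) -> list[float | None]:
    """Family-wise/FDR-adjusted p-values across the emitted rows.

    Not part of the standard output — the primary analysis reports unadjusted
    empirical p-values; this is an optional sensitivity layer
    ("bonferroni" or "bh" via statsmodels).
    """
    from statsmodels.stats.multitest import multipletests

    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    idx = [i for i, r in enumerate(results) if r.p is not None]
    adjusted: list[float | None] = [None] * len(results)
    if idx:
        _, adj, _, _ = multipletests([results[i].p for i in idx], method=key)
        for i, a in zip(idx, adj):
            adjusted[i] = float(a)
    return adjusted


def kde_tau(
    null_taus: np.ndarray, tau_obs: float, gridsize: int = 512
) -> tuple[np.ndarray, np.ndarray, float]:
    """Gaussian KDE of the null slopes (Silverman bandwidth) plus the observed marker.

    Returns (grid, density, tau_obs); the density integrates to 1 within 1e-3
    over the returned grid.  Diagnostic only — never enters the p-value.
    """
    from scipy.stats import gaussian_kde

    null_taus = np.asarray(null_taus, dtype=float)
    if null_taus.size < 2:
        raise ValueError("KDE needs at least 2 null values")
    if np.ptp(null_taus) == 0:
        raise ValueError("degenerate (zero-variance) null distribution")
    kde = gaussian_kde(null_taus, bw_method="silverman")
    lo = min(null_taus.min(), tau_obs) - 4 * kde.factor * null_taus.std()
    hi = max(null_taus.max(), tau_obs) + 4 * kde.factor * null_taus.std()
    grid = np.linspace(lo, hi, gridsize)
    return grid, kde(grid), float(tau_obs)


def plot_kde(result: Stage1Result, path: str | Path) -> None:
    """Write the null-density diagnostic plot with the observed tau marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid, dens, obs = kde_tau(result.null_taus, result.tau_obs)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(grid, dens, lw=1.5, label="resampled null")
    ax.axvline(obs, color="crimson", ls="--", lw=1.2, label=f"observed τ = {obs:.3f}")
    ax.set_xlabel("τ (slope of offspring trait on parental trait)")
    ax.set_ylabel("density")
    ax.set_title(f"{result.spec.trait_name} {result.spec.generation_pair.value}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def write_stage1_tsv(
    results: list[Stage1Result],
    path: str | Path,
    adjusted: Sequence[float | None] | None = None,
) -> None:
    """Write the Stage 1 report: Outcome, Exposure, Observed effect, c, n, P value.

    ``adjusted``, if given, adds a multiplicity-adjusted column (an optional
    sensitivity output, not part of the standard report).
    """
    label = {
        GenerationPair.GC_ON_GP: ("GC", "GP"),
        GenerationPair.GC_ON_P: ("GC", "P"),
        GenerationPair.P_ON_GP: ("P", "GP"),
    }
    rows = []
    for i, r in enumerate(results):
        out, exp = label[r.spec.generation_pair]
        row = {
            "Outcome": f"{r.spec.trait_name}—{out}",
            "Exposure": f"{r.spec.trait_name}—{exp}",
            "Observed effect": "" if r.tau_obs is None else f"{r.tau_obs:.3f}",
            "c": "" if r.c is None else r.c,
            "n": "" if r.n is None else r.n,
            "P value": "" if r.p is None else f"{r.p:.4f}",
            "note": r.message,
        }
        if adjusted is not None:
            a = adjusted[i]
            row["Adjusted P"] = "" if a is None else f"{a:.4f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
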