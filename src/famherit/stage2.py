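"""Stage 2: variance-component heritability under the pedigree LMM.

Model: y | X ~ N(X beta, sigma_g2 * G + sigma_e2 * I) where G is the pedigree
genetic relatedness matrix, sigma_g2 the polygenic (additive genetic)
variance and sigma_e2 the residual variance; heritability is
h2 = sigma_g2 / (sigma_g2 + sigma_e2).  The trait and the age covariate are
standardised together before estimation.

Three fitters share the same eigen-rotated representation of the model
(G = U D U'; in the rotated basis the covariance is diagonal):

* :class:`PedigreeReML` — restricted maximum likelihood by 1-D profile
  optimisation in lambda = sigma_g2/sigma_e2, boundary estimates permitted;
* :class:`PedigreeGibbs` — systematic-scan Gibbs sampling of the hierarchical
  model with N(0, beta_sd^2) priors on fixed effects and InvGamma(s1, s2)
  priors on both variances;
* :class:`PedigreeHMC` — Hamiltonian Monte Carlo with leapfrog integration on
  the marginalised posterior of (beta, log sigma_g2, log sigma_e2), step size
  tuned by dual averaging during burn-in.

All three are sklearn-style estimators: ``fit(X, y, G=...)`` with fitted
attributes carrying a trailing underscore.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .pedigree import RelatednessMatrix

__all__ = [
    "LmmSpec",
    "PriorSpec",
    "VarianceComponents",
    "HeritabilityEstimate",
    "PosteriorSamples",
    "standardize",
    "make_lmm_spec",
    "restricted_loglik",
    "reml_fit",
    "gibbs_fit",
    "hmc_fit",
    "h2_from_components",
    "lrt_h2",
    "estimate_power",
    "PedigreeReML",
    "PedigreeGibbs",
    "PedigreeHMC",
]


def standardize(v: np.ndarray) -> np.ndarray:
    """Centre and scale to mean 0, sample (ddof=1) variance 1."""
    v = np.asarray(v, dtype=float)
    s = v.std(ddof=1)
    if not np.isfinite(s) or s == 0:
        raise ValueError("cannot standardize a constant (zero-variance) vector")
    return (v - v.mean()) / s


def h2_from_components(sigma_g2: float, sigma_e2: float) -> float:
    """Narrow-sense heritability sigma_g2 / (sigma_g2 + sigma_e2)."""
    if sigma_g2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be non-negative")
    tot = sigma_g2 + sigma_e2
    if tot == 0:
        raise ValueError("both variance components are zero; h2 undefined")
    return sigma_g2 / tot


@dataclass(frozen=True)
class LmmSpec:
    """Aligned (y, X, G) for the pedigree LMM; y and age pre-standardised."""

    y: np.ndarray
    X: np.ndarray
    G: np.ndarray
    ids: tuple[str, ...] = ()
    covariate_names: tuple[str, ...] = ("intercept", "age")

    def __post_init__(self) -> None:
        n = self.y.shape[0]
        if self.X.shape[0] != n or self.G.shape != (n, n):
            raise ValueError("y, X rows and G must align")
        if n <= self.X.shape[1]:
            raise ValueError("need more observations than fixed effects")


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the Bayesian fitters.

    Fixed effects beta_j ~ N(0, beta_sd^2) with beta_sd = 1000 by default
    (effectively flat on the standardised scale); both variance components
    get InvGamma(s1, s2) with s1 = s2 = 0.001 as a conventional
    non-informative choice.
    """

    beta_sd: float = 1000.0
    s1: float = 0.001
    s2: float = 0.001

    def __post_init__(self) -> None:
        if self.beta_sd <= 0 or self.s1 <= 0 or self.s2 <= 0:
            raise ValueError("prior hyperparameters must be positive")


@dataclass
class VarianceComponents:
    """Point estimates (with SDs) of the LMM variance components."""

    sigma_g2: float
    sigma_e2: float
    method: str
    sigma_g2_sd: float | None = None
    sigma_e2_sd: float | None = None
    phenotypic_sd: float | None = None
    beta: np.ndarray | None = None
    beta_sd: np.ndarray | None = None
    h2: float = 0.0
    h2_sd: float | None = None
    loglik: float | None = None
    boundary: bool = False

    @property
    def phenotypic(self) -> float:
        return self.sigma_g2 + self.sigma_e2


@dataclass(frozen=True)
class HeritabilityEstimate:
    h2: float
    sd: float | None
    method: str


@dataclass
class PosteriorSamples:
    """Kept MCMC draws with the per-draw heritability and chain diagnostics."""

    beta: np.ndarray  # (n_kept, p)
    sigma_g2: np.ndarray
    sigma_e2: np.ndarray
    h2: np.ndarray
    n_total: int
    n_kept: int
    method: str
    accept_rate: float | None = None
    step_size: float | None = None
    divergence_rate: float = 0.0

    def diagnostics(self) -> dict[str, float]:
        """Effective sample size and split-R-hat of the h2 chain (via arviz)."""
        import arviz as az

        half = self.n_kept // 2
        split = self.h2[: 2 * half].reshape(2, half)  # (chain, draw)
        ds = az.convert_to_dataset(split)
        return {
            "ess_h2": float(az.ess(ds)["x"].values),
            "split_rhat_h2": float(az.rhat(ds)["x"].values),
        }

    def summarize(self) -> VarianceComponents:
        """Posterior means and SDs; h2 summarised as the per-draw ratio."""
        return VarianceComponents(
            sigma_g2=float(self.sigma_g2.mean()),
            sigma_e2=float(self.sigma_e2.mean()),
            sigma_g2_sd=float(self.sigma_g2.std(ddof=1)),
            sigma_e2_sd=float(self.sigma_e2.std(ddof=1)),
            phenotypic_sd=float((self.sigma_g2 + self.sigma_e2).std(ddof=1)),
            beta=self.beta.mean(axis=0),
            beta_sd=self.beta.std(axis=0, ddof=1),
            h2=float(self.h2.mean()),
            h2_sd=float(self.h2.std(ddof=1)),
            method=self.method,
        )


def make_lmm_spec(
    dataset: pd.DataFrame,
    relatedness: RelatednessMatrix,
    trait: str,
    covariates: Sequence[str] = ("age",),
) -> LmmSpec:
    """Build an aligned LmmSpec from a phenotype table and a GRM.

    Rows missing the trait or any covariate are dropped; the trait and each
    covariate are standardised; G is restricted to the retained individuals.
    """
    cols = ["individual_id", trait, *covariates]
    sub = dataset.loc[:, cols].dropna()
    if len(sub) < len(covariates) + 2:
        raise ValueError(f"too few complete observations for trait {trait!r}")
    ids = [str(i) for i in sub["individual_id"]]
    y = standardize(sub[trait].to_numpy(dtype=float))
    X = np.column_stack(
        [np.ones(len(sub))]
        + [standardize(sub[c].to_numpy(dtype=float)) for c in covariates]
    )
    Gr = relatedness.reorder(ids)
    return LmmSpec(
        y=y, X=X, G=Gr.G, ids=tuple(ids), covariate_names=("intercept", *covariates)
    )


# ---------------------------------------------------------------------------
# Eigen-rotated representation
# ---------------------------------------------------------------------------


class _EigenLMM:
    """The LMM rotated into the eigenbasis of G (covariance diagonal there)."""

    def __init__(self, y: np.ndarray, X: np.ndarray, G: np.ndarray):
        d, U = np.linalg.eigh(G)
        if d.min() < -1e-8:
            raise ValueError(f"G is not PSD (min eigenvalue {d.min():.3g})")
        self.d = np.clip(d, 0.0, None)
        self.U = U
        self.y = U.T @ y
        self.X = U.T @ X
        self.n, self.p = X.shape

    def restricted_loglik(self, sigma_g2: float, sigma_e2: float) -> float:
        """l_R = -1/2 [(n-p) ln 2pi + ln|V| + ln|X'V^-1 X| + y'Py]."""
        v = sigma_g2 * self.d + sigma_e2
        if np.any(v <= 0):
            return -np.inf
        Xv = self.X / v[:, None]
        XtVX = self.X.T @ Xv
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(XtVX, Xv.T @ self.y)
        r = self.y - self.X @ beta
        quad = float(np.sum(r * r / v))
        return -0.5 * (
            (self.n - self.p) * math.log(2 * math.pi)
            + float(np.sum(np.log(v)))
            + logdet_xvx
            + quad
        )

    def profile(self, lam: float) -> tuple[float, float]:
        """Profile restricted loglik over sigma_e2 at fixed lambda = sg2/se2."""
        v1 = lam * self.d + 1.0
        Xv = self.X / v1[:, None]
        XtVX = self.X.T @ Xv
        beta = np.linalg.solve(XtVX, Xv.T @ self.y)
        r = self.y - self.X @ beta
        quad1 = float(np.sum(r * r / v1))
        df = self.n - self.p
        se2 = quad1 / df
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        ll = -0.5 * (
            df * math.log(2 * math.pi)
            + df * math.log(se2)
            + float(np.sum(np.log(v1)))
            + logdet_xvx
            + df
        )
        return ll, se2

    def gls(self, sigma_g2: float, sigma_e2: float) -> tuple[np.ndarray, np.ndarray]:
        v = sigma_g2 * self.d + sigma_e2
        Xv = self.X / v[:, None]
        XtVX = self.X.T @ Xv
        cov = np.linalg.inv(XtVX)
        beta = cov @ (Xv.T @ self.y)
        return beta, cov


def restricted_loglik(
    spec: LmmSpec, sigma_g2: float, sigma_e2: float
) -> float:
    """Restricted log-likelihood of (sigma_g2, sigma_e2) for the spec."""
    return _EigenLMM(spec.y, spec.X, spec.G).restricted_loglik(sigma_g2, sigma_e2)


# ---------------------------------------------------------------------------
# ReML
# ---------------------------------------------------------------------------


def _reml_core(eig: _EigenLMM) -> VarianceComponents:
    # coarse grid over the variance ratio, then Brent refinement in log-lambda
    lams = np.concatenate([[0.0], np.logspace(-4, 4, 41)])
    lls = np.array([eig.profile(l)[0] for l in lams])
    k = int(np.argmax(lls))
    if k == 0:
        lam_hat = 0.0
    else:
        lo = math.log(lams[max(k - 1, 1)])
        hi = math.log(lams[min(k + 1, len(lams) - 1)])
        if lo == hi:
            lam_hat = lams[k]
        else:
            res = optimize.minimize_scalar(
                lambda t: -eig.profile(math.exp(t))[0],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-10},
            )
            lam_hat = math.exp(res.x)
            if eig.profile(0.0)[0] >= -res.fun:
                lam_hat = 0.0
    ll, se2 = eig.profile(lam_hat)
    sg2 = lam_hat * se2
    boundary = lam_hat == 0.0

    beta, bcov = eig.gls(sg2, se2)
    vc = VarianceComponents(
        sigma_g2=sg2,
        sigma_e2=se2,
        method="ReML",
        beta=beta,
        beta_sd=np.sqrt(np.diag(bcov)),
        loglik=ll,
        boundary=boundary,
        h2=h2_from_components(sg2, se2),
    )
    if not boundary:
        H = _neg_hessian(eig, sg2, se2)
        try:
            cov = np.linalg.inv(H)
            if np.all(np.diag(cov) > 0):
                vc.sigma_g2_sd = math.sqrt(cov[0, 0])
                vc.sigma_e2_sd = math.sqrt(cov[1, 1])
                vc.phenotypic_sd = math.sqrt(cov.sum())
                grad = np.array(
                    [se2 / (sg2 + se2) ** 2, -sg2 / (sg2 + se2) ** 2]
                )
                var_h2 = float(grad @ cov @ grad)
                vc.h2_sd = math.sqrt(var_h2) if var_h2 > 0 else None
        except np.linalg.LinAlgError:
            pass
    return vc


def _neg_hessian(eig: _EigenLMM, sg2: float, se2: float) -> np.ndarray:
    """Observed information: central finite differences of -l_R."""
    h1 = max(1e-5, 1e-4 * max(sg2, 1e-3))
    h2_ = max(1e-5, 1e-4 * se2)
    steps = (h1, h2_)

    def f(a: float, b: float) -> float:
        return eig.restricted_loglik(max(a, 1e-12), max(b, 1e-12))

    H = np.zeros((2, 2))
    x = (sg2, se2)
    for i in range(2):
        for j in range(2):
            hi_, hj = steps[i], steps[j]
            if i == j:
                pp = list(x)
                pp[i] += hi_
                mm = list(x)
                mm[i] -= hi_
                H[i, i] = -(f(*pp) - 2 * f(*x) + f(*mm)) / hi_**2
            else:
                a = list(x); a[i] += hi_; a[j] += hj
                b = list(x); b[i] += hi_; b[j] -= hj
                c = list(x); c[i] -= hi_; c[j] += hj
                e = list(x); e[i] -= hi_; e[j] -= hj
                H[i, j] = -(f(*a) - f(*b) - f(*c) + f(*e)) / (4 * hi_ * hj)
    return 0.5 * (H + H.T)


def reml_fit(spec: LmmSpec) -> VarianceComponents:
    """ReML variance components by profile optimisation in lambda = sg2/se2.

    Boundary estimates (sigma_g2 = 0) are permitted; there the curvature-based
    SDs are reported as None.
    """
    return _reml_core(_EigenLMM(spec.y, spec.X, spec.G))


def lrt_h2(spec: LmmSpec) -> tuple[float, float]:
    """Boundary likelihood-ratio test of sigma_g2 = 0.

    Statistic 2(l_full - l_null) referred to the 50:50 mixture chi2_0/chi2_1
    null appropriate when the tested value sits on the parameter boundary.
    """
    eig = _EigenLMM(spec.y, spec.X, spec.G)
    full = _reml_core(eig)
    ll_null, _ = eig.profile(0.0)
    stat = max(0.0, 2.0 * (full.loglik - ll_null))
    p = 1.0 if stat == 0.0 else 0.5 * stats.chi2.sf(stat, df=1)
    return stat, float(p)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def gibbs_fit(
    spec: LmmSpec,
    priors: PriorSpec | None = None,
    n_iter: int = 100_000,
    burn_in: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
) -> PosteriorSamples:
    """Systematic-scan Gibbs sampler for the hierarchical pedigree LMM.

    The polygenic vector is rotated into the eigenbasis of G, where its prior
    precision is diagonal, so every full conditional is sampled exactly:
    beta | . (Gaussian), g | . (independent Gaussians in the rotated basis),
    sigma_g2 | g ~ InvGamma(s1 + n/2, s2 + g'G^-1 g / 2) and
    sigma_e2 | residuals ~ InvGamma(s1 + n/2, s2 + e'e / 2).
    Keeps the last ``n_iter - burn_in`` draws.
    """
    priors = priors or PriorSpec()
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    eig = _EigenLMM(spec.y, spec.X, spec.G)
    n, p = eig.n, eig.p
    d = np.clip(eig.d, 1e-12, None)  # pedigree GRMs here are PD
    X, y = eig.X, eig.y
    XtX = X.T @ X
    rng = np.random.default_rng(seed)

    s1, s2 = priors.s1, priors.s2
    prior_prec_beta = 1.0 / priors.beta_sd**2
    shape = s1 + n / 2.0

    beta = np.zeros(p)
    g = np.zeros(n)
    sg2 = se2 = 0.5 * float(y.var())

    n_keep = n_iter - burn_in
    out_beta = np.empty((n_keep, p))
    out_sg2 = np.empty(n_keep)
    out_se2 = np.empty(n_keep)

    eye_p = np.eye(p)
    for it in range(n_iter):
        # beta | g, se2
        prec = XtX / se2 + prior_prec_beta * eye_p
        L = np.linalg.cholesky(prec)
        mu = np.linalg.solve(prec, X.T @ (y - g) / se2)
        beta = mu + np.linalg.solve(L.T, rng.standard_normal(p))
        # rotated polygenic values: independent given everything else
        resid = y - X @ beta
        gprec = 1.0 / se2 + 1.0 / (sg2 * d)
        gmu = (resid / se2) / gprec
        g = gmu + rng.standard_normal(n) / np.sqrt(gprec)
        # variance components
        sg2 = 1.0 / rng.gamma(shape, 1.0 / (s2 + 0.5 * float(np.sum(g * g / d))))
        e = resid - g
        se2 = 1.0 / rng.gamma(shape, 1.0 / (s2 + 0.5 * float(e @ e)))
        if not (np.isfinite(sg2) and np.isfinite(se2)):
            raise RuntimeError(f"Gibbs chain diverged at iteration {it}")
        if it >= burn_in:
            k = it - burn_in
            out_beta[k] = beta
            out_sg2[k] = sg2
            out_se2[k] = se2

    return PosteriorSamples(
        beta=out_beta,
        sigma_g2=out_sg2,
        sigma_e2=out_se2,
        h2=out_sg2 / (out_sg2 + out_se2),
        n_total=n_iter,
        n_kept=n_keep,
        method="MCMC",
    )


# ---------------------------------------------------------------------------
# Hamiltonian Monte Carlo
# ---------------------------------------------------------------------------


def _hmc_logpost_grad(
    theta: np.ndarray, eig: _EigenLMM, priors: PriorSpec
) -> tuple[float, np.ndarray]:
    """Log posterior and gradient in (beta, u = ln sg2, w = ln se2).

    The polygenic vector is integrated out analytically, leaving the marginal
    likelihood y ~ N(X beta, diag(sg2 d + se2)) in the rotated basis.  The
    InvGamma priors with the log-Jacobian reduce to -s1*t - s2*exp(-t) in
    each log-variance t.
    """
    p = eig.p
    beta, u, w = theta[:p], theta[p], theta[p + 1]
    if not np.all(np.isfinite(theta)) or abs(u) > 50 or abs(w) > 50:
        # runaway leapfrog excursion: flag as divergent
        return -np.inf, np.zeros_like(theta)
    sg2, se2 = math.exp(u), math.exp(w)
    v = sg2 * eig.d + se2
    r = eig.y - eig.X @ beta
    rv = r / v
    ll = -0.5 * (eig.n * math.log(2 * math.pi) + float(np.sum(np.log(v))) + float(r @ rv))
    s1, s2 = priors.s1, priors.s2
    lp = (
        ll
        - 0.5 * float(beta @ beta) / priors.beta_sd**2
        - s1 * u
        - s2 * math.exp(-u)
        - s1 * w
        - s2 * math.exp(-w)
    )
    grad = np.empty_like(theta)
    grad[:p] = eig.X.T @ rv - beta / priors.beta_sd**2
    common = rv * rv - 1.0 / v
    grad[p] = 0.5 * sg2 * float(common @ eig.d) - s1 + s2 * math.exp(-u)
    grad[p + 1] = 0.5 * se2 * float(np.sum(common)) - s1 + s2 * math.exp(-w)
    return lp, grad


def hmc_fit(
    spec: LmmSpec,
    priors: PriorSpec | None = None,
    n_iter: int = 100_000,
    burn_in: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
    n_leapfrog: int = 20,
    target_accept: float = 0.8,
) -> PosteriorSamples:
    """HMC with leapfrog integration on the marginalised posterior.

    Parameters are (beta, ln sigma_g2, ln sigma_e2) with the polygenic vector
    integrated out through the eigenbasis of G; the log-scale change of
    variables carries its Jacobian.  Step size is adapted by dual averaging
    towards ``target_accept`` during burn-in and frozen afterwards.  Raises if
    more than 5% of post-warmup trajectories diverge.
    """
    priors = priors or PriorSpec()
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    eig = _EigenLMM(spec.y, spec.X, spec.G)
    p = eig.p
    rng = np.random.default_rng(seed)

    theta = np.zeros(p + 2)
    theta[p] = theta[p + 1] = math.log(0.5 * float(eig.y.var()) + 1e-12)
    lp, grad = _hmc_logpost_grad(theta, eig, priors)

    # dual averaging (Nesterov-style) as in adaptive HMC samplers
    eps = 0.1
    mu = math.log(10 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    n_keep = n_iter - burn_in
    out_beta = np.empty((n_keep, p))
    out_sg2 = np.empty(n_keep)
    out_se2 = np.empty(n_keep)
    n_accept = 0
    n_div_post = 0

    for it in range(n_iter):
        mom = rng.standard_normal(p + 2)
        H0 = lp - 0.5 * float(mom @ mom)
        th, gr = theta.copy(), grad.copy()
        mom_ = mom + 0.5 * eps * gr
        diverged = False
        for step in range(n_leapfrog):
            th = th + eps * mom_
            lp_new, gr = _hmc_logpost_grad(th, eig, priors)
            if not np.isfinite(lp_new):
                diverged = True
                break
            mom_ = mom_ + (eps if step < n_leapfrog - 1 else 0.5 * eps) * gr
        if not diverged:
            H1 = lp_new - 0.5 * float(mom_ @ mom_)
            delta = H1 - H0
            diverged = delta < -1000.0
        accept_prob = 0.0 if diverged else min(1.0, math.exp(min(delta, 0.0)))
        if (not diverged) and rng.random() < accept_prob:
            theta, lp, grad = th, lp_new, gr
            n_accept += 1
        if it < burn_in:
            m = it + 1
            h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - accept_prob) / (m + t0)
            log_eps = mu - math.sqrt(m) / gamma * h_bar
            eta = m**-kappa
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = math.exp(log_eps)
            if it == burn_in - 1:
                eps = math.exp(log_eps_bar)
        else:
            if diverged:
                n_div_post += 1
            k = it - burn_in
            out_beta[k] = theta[:p]
            out_sg2[k] = math.exp(theta[p])
            out_se2[k] = math.exp(theta[p + 1])

    if n_keep > 0 and n_div_post / n_keep > 0.05:
        raise RuntimeError(
            f"HMC diverged on {n_div_post}/{n_keep} post-warmup trajectories"
        )
    return PosteriorSamples(
        beta=out_beta,
        sigma_g2=out_sg2,
        sigma_e2=out_se2,
        h2=out_sg2 / (out_sg2 + out_se2),
        n_total=n_iter,
        n_kept=n_keep,
        method="HMC",
        accept_rate=n_accept / n_iter,
        step_size=eps,
        divergence_rate=n_div_post / max(n_keep, 1),
    )


# ---------------------------------------------------------------------------
# Power by simulation
# ---------------------------------------------------------------------------


def estimate_power(
    n_families: int = 65,
    h2_true: float = 0.4,
    alpha: float = 0.05,
    n_reps: int = 500,
    seed: int | np.random.SeedSequence | None = 0,
    beta_age: float = 0.0,
) -> tuple[float, float]:
    """Power of the boundary LRT for sigma_g2 = 0 at a trio-family design.

    Simulates ``n_reps`` maternal-line trio datasets with total phenotypic
    variance 1 (sigma_g2 = h2_true), fits the age-adjusted LMM by ReML, and
    applies the chi2_0/chi2_1 mixture LRT at level alpha.  Returns the
    rejection fraction and its binomial Monte-Carlo SE.  This is a simulation
    analogue of an analytic power calculation, not a closed form.
    """
    from .simulate import SyntheticConfig, generate_pedigree, sample_breeding_values

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    root = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    ped_seed, *rep_seeds = root.spawn(n_reps + 1)
    ped = generate_pedigree(n_families, seed=ped_seed)
    from .pedigree import grm as _grm

    G = _grm(ped).G
    d, U = np.linalg.eigh(G)
    n = len(ped)
    rejections = 0
    for ss in rep_seeds:
        rng = np.random.default_rng(ss)
        g = sample_breeding_values(ped, sigma_g2=h2_true, seed=rng)
        age = rng.normal(size=n)
        y = beta_age * age + g + rng.normal(scale=math.sqrt(1 - h2_true) if h2_true < 1 else 0.0, size=n)
        spec = LmmSpec(
            y=standardize(y),
            X=np.column_stack([np.ones(n), standardize(age)]),
            G=G,
        )
        _, pval = lrt_h2(spec)
        rejections += pval < alpha
    power = rejections / n_reps
    mc_se = math.sqrt(power * (1 - power) / n_reps)
    return power, mc_se


# ---------------------------------------------------------------------------
# Estimator classes
# ---------------------------------------------------------------------------


class _PedigreeLmmBase(BaseEstimator):
    @staticmethod
    def _spec(X, y, G) -> LmmSpec:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if G is None:
            raise ValueError("a relatedness matrix G must be passed to fit")
        G = G.G if isinstance(G, RelatednessMatrix) else np.asarray(G, dtype=float)
        return LmmSpec(y=y, X=X, G=G)


class PedigreeReML(_PedigreeLmmBase):
    """ReML heritability estimator for a pedigree LMM.

    ``fit(X, y, G=...)`` with X the fixed-effects design (include the
    intercept column) and G the genetic relatedness matrix aligned with the
    rows.  Fitted attributes: ``sigma_g2_``, ``sigma_e2_``, ``h2_``,
    ``h2_sd_``, ``beta_``, ``components_`` (the full
    :class:`VarianceComponents`).
    """

    def fit(self, X, y, G=None):
        vc = reml_fit(self._spec(X, y, G))
        self.components_ = vc
        self.sigma_g2_, self.sigma_e2_ = vc.sigma_g2, vc.sigma_e2
        self.h2_, self.h2_sd_ = vc.h2, vc.h2_sd
        self.beta_ = vc.beta
        return self

    def score(self, X=None, y=None) -> float:
        check_is_fitted(self, "components_")
        return float(self.components_.loglik)


class _PedigreeSamplerBase(_PedigreeLmmBase):
    def _finalize(self, samples: PosteriorSamples):
        self.samples_ = samples
        vc = samples.summarize()
        self.components_ = vc
        self.sigma_g2_, self.sigma_e2_ = vc.sigma_g2, vc.sigma_e2
        self.h2_, self.h2_sd_ = vc.h2, vc.h2_sd
        self.beta_ = vc.beta
        return self


class PedigreeGibbs(_PedigreeSamplerBase):
    """Gibbs-sampling Bayesian heritability estimator (see :func:`gibbs_fit`)."""

    def __init__(
        self,
        n_iter: int = 100_000,
        burn_in: int = 10_000,
        priors: PriorSpec | None = None,
        random_state: int | None = None,
    ) -> None:
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.priors = priors
        self.random_state = random_state

    def fit(self, X, y, G=None):
        return self._finalize(
            gibbs_fit(
                self._spec(X, y, G),
                priors=self.priors,
                n_iter=self.n_iter,
                burn_in=self.burn_in,
                seed=self.random_state,
            )
        )


class PedigreeHMC(_PedigreeSamplerBase):
    """HMC Bayesian heritability estimator (see :func:`hmc_fit`)."""

    def __init__(
        self,
        n_iter: int = 100_000,
        burn_in: int = 10_000,
        priors: PriorSpec | None = None,
        n_leapfrog: int = 20,
        target_accept: float = 0.8,
        random_state: int | None = None,
    ) -> None:
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.priors = priors
        self.n_leapfrog = n_leapfrog
        self.target_accept = target_accept
        self.random_state = random_state

    def fit(self, X, y, G=None):
        return self._finalize(
            hmc_fit(
                self._spec(X, y, G),
                priors=self.priors,
                n_iter=self.n_iter,
                burn_in=self.burn_in,
                seed=self.random_state,
                n_leapfrog=self.n_leapfrog,
                target_accept=self.target_accept,
            )
        )
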