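# Methods

This note records the statistical model, the numerical choices and the
limits of what the test suite demonstrates.

## Data model

One row per individual: identity (`individual_id`, `family_id`), generation
role (grandparent / parent / child), sex, maternal link (`mother_id`),
covariates (age in years, height in cm, weight in kg, waist and mid-upper-arm
circumference in cm) and the vascular measures (pressures in mm Hg, PWV in
m/s, cIMT in mm, echo dimensions in cm, LVM in g, LVMI in g/m²). Missing
values stay missing: every derived phenotype propagates missingness and
nothing is imputed.

Derived-phenotype rules: triplicate BP readings are reduced to the mean of
readings 2 and 3 (the first absorbs the alerting response); adult BMI
categories use [18.5, 25) normal and [25, 30) overweight so the 24.95 case
has a home; adult BP status is hypertension at ≥140/≥90 or on medication,
prehypertension at [120,140)/[80,90); hazardous alcohol use is AUDIT-C ≥ 3
or total AUDIT ≥ 8; LVM follows the cube-formula Devereux–Reichek correction
0.8·1.04·((IVSd+LVIDd+PWd)³ − LVIDd³) + 0.6 g; BSA defaults to Mosteller
(√(h·w/3600)) with Du Bois selectable, because the LVMI thresholds
(adults > 95 g/m², children above the tabulated 95th percentile, 109.4 g/m²)
are sensitive to the BSA formula. Child BMI and BP classification interfaces
take replaceable reference tables; the bundled YAML is a clearly labelled
synthetic stand-in with the documented schema, not the published IOTF/AAP
values, and a value at a cut-off enters the higher category.

## Pedigree and relatedness

Pedigrees are maternal-line chains; fathers are structurally absent. Kinship
uses the recursive tabular algorithm (φ_ii = (1+φ_mf)/2,
φ_ij = (φ_mother(i),j + φ_father(i),j)/2, unknown parents contributing 0) and
G = 2φ. For these pedigrees G is block-diagonal with identical 3×3 trio
blocks [[1,.5,.25],[.5,1,.5],[.25,.5,1]], positive definite. Inbred loops
cannot occur in this design, so an inbred mating raises instead of silently
computing. Files use the PLINK `.fam`-compatible five-column format.

## Stage 1: randomisation inference

The null is built by **derangement-constrained** permutation: "random
families" are only ever non-biological pairings, so no resample reproduces an
original pair. Unrestricted permutation is available behind
`permutation="free"` for sensitivity analysis. Covariates (the offspring's;
an option adds the exposure side's) stay attached to the outcome rows.

Two numerical points:

* Slopes for permuted exposures are computed through the
  Frisch–Waugh–Lovell projection: with M the residual-maker of the fixed
  covariate design, τ_π = (Mz_π)′y / ‖Mz_π‖². This is algebraically the OLS
  coefficient from refitting the full regression per permutation (asserted in
  tests to 1e-9) and makes the 5000-resample runs and the calibration study
  cheap.
* p = c/n exactly, ties counted, no +1 correction, so p = 0 can occur.

Covariate sets follow the trait registry (age, height, weight, sex for the
pressure/stiffness/cIMT traits; age and sex for LVMI, which is already
body-size indexed). When a registry covariate is constant within a pair table
— sex, whenever the offspring generation is all-female by the maternal-line
design — the pipeline drops it for that row and records the drop, while the
low-level `fit_tau` keeps its strict contract and raises on constant columns.
Per-row seeds are spawned from the master seed (`SeedSequence.spawn`), so any
single row is reproducible without rerunning the rest.

Kernel density plots of the null slopes (Gaussian kernel, Silverman
bandwidth) are diagnostics only; nothing downstream depends on the bandwidth.

## Stage 2: variance components

The trait and age (the only Stage 2 covariate) are standardised together to
sample mean 0, sample variance 1. All three fitters work in the eigenbasis of
G (G = UDU′), where the covariance σ_g²D + σ_e²I is diagonal.

**ReML.** The restricted log-likelihood
ℓ_R = −½[(n−p)·ln 2π + ln|V| + ln|X′V⁻¹X| + y′Py] is profiled in
λ = σ_g²/σ_e² (closed-form σ̂_e² given λ), maximised on a coarse log-spaced
grid including the λ = 0 boundary and refined by bounded Brent search.
Curvature-based SDs come from a central finite-difference observed
information at an interior optimum and the delta method for h²; at the
boundary (σ̂_g² = 0) SDs are reported as unavailable rather than as a Wald
number. The boundary LRT for σ_g² = 0 uses the 50:50 χ²₀/χ²₁ mixture null.

**Gibbs.** Priors β_j ~ N(0, 1000²) and σ_g², σ_e² ~ InvGamma(s₁, s₂) with
s₁ = s₂ = 0.001 as a conventional non-informative default (configurable; a
prior-sensitivity test verifies the posterior barely moves at 10× the scale).
Rotating the polygenic vector into the eigenbasis makes its full conditional
a product of independent Gaussians, so the scan is exact and O(n) per sweep:
β | ·, g̃ | ·, σ_g² | g ~ InvGamma(s₁+n/2, s₂+g′G⁻¹g/2),
σ_e² | e ~ InvGamma(s₁+n/2, s₂+e′e/2). Defaults are 100 000 iterations with
the first 10 000 discarded. h² is recorded per draw as σ_g²/(σ_g²+σ_e²) and
summarised as the posterior mean (SD) of that ratio, not the ratio of means.
The h² chain mixes slowly in weakly identified designs (the σ_g² ↔ g
coupling), which is exactly why the default chain is long; effective sample
size and split-R̂ are exposed via `PosteriorSamples.diagnostics()`.

**HMC.** The polygenic vector is integrated out analytically, leaving the
marginal likelihood y ~ N(Xβ, σ_g²G + σ_e²I) over (β, ln σ_g², ln σ_e²) with
the log-scale Jacobian folded into the priors (each log-variance contributes
−s₁t − s₂e^(−t)). Leapfrog integration uses 20 steps; the step size is tuned
by dual averaging towards 0.8 acceptance during burn-in and frozen after.
Trajectories with non-finite log-posterior or energy error beyond 1000 are
divergences; more than 5% post-warmup divergences is an error. Gradients are
analytic and verified against finite differences.

G is positive definite by construction for these pedigrees; eigenvalues are
clipped at 0 and a 1e-12 floor guards the Gibbs division. No diagonal jitter
is needed in practice.

**Power.** `estimate_power` simulates trio cohorts at a given true h²
(total phenotypic variance 1), fits the age-adjusted LMM and applies the
boundary LRT. It is a simulation analogue of an analytic power calculation
— at the 65-family design it gives roughly 0.75 at h² = 0.4 and 0.90 at
h² = 0.5 with the mixture LRT at α = 0.05, the same order as published
analytic figures for designs of this size, and those exact figures are not a
target. The mixture-LRT type-I rate at this n runs a shade above nominal
(≈0.05–0.08), a known finite-sample property of the boundary approximation.

## Synthetic data

The generator's defaults emulate the study conditions: 65 maternal-line
trios (195 individuals), child sex Bernoulli(36/65 female), generation ages
centred at 56 / 29 / 7, per-measure missingness matched to the per-measure
completion counts (e.g. PWV 57/61/56 of 65), trait locations and scales
tracking the descriptive medians and IQR/1.35, and heritabilities of 0.35
(cIMT), 0.30 (LVMI) and 0.10 (pressures, PWV) — mid-range published values
for the structural traits, deliberately weak transmission for the
functional ones.

Breeding values descend the pedigree with Mendelian segregation noise:
founders N(0, σ_g²); with only the mother known, g = g_mother/2 +
N(0, ¾σ_g²), so the marginal variance is σ_g² and Cov(g) = σ_g²G (checked
against an empirical covariance over 20 000 replicate trios and against
gene-dropping Monte Carlo). Traits are latent-scale
β_age·age_z + β_sex·male + g + e rescaled per generation; heritability is
invariant to that affine rescaling. All randomness flows from one seed
through fixed-order `SeedSequence` spawns, so datasets regenerate bit-exactly.

What the generator does **not** emulate: shared-household (common
environment) variance — the generated h² is purely additive, whereas a
pedigree estimate on real families confounds additive genetics with shared
environment; device-level measurement error structure; assortative mating;
paternal relatedness. Passing recovery tests therefore show the estimators
are correct under the additive model, not that real-cohort estimates are
free of environmental confounding.

## Test scaling

The suite runs the same code paths as production with smaller problem sizes,
chosen as the smallest that make the statistical assertions sharp: sampler
chains of 1 500–10 000 draws instead of 100 000; 200-replicate recovery
studies; 1000 × 500 for the null-calibration study; 20 000 families for the
large-sample regression limits; 100 000 replicates for gene-dropping.
Monte-Carlo tolerances are 3 standard errors of the quantity under test, and
sampler agreement uses batch-means MC errors, which stay honest under the
Gibbs chain's autocorrelation.

## Known limitations

* The boundary-truncated ReML h² estimator has positive bias at small true
  h² (mean ≈ 0.4 × SE at h² = 0, i.e. ≈ 0.06 at the 65-trio design); the
  median is unbiased at the boundary. This is a property of the estimator,
  not of the implementation.
* Gibbs h² mixing is slow in weakly identified designs; use the long default
  chains or the HMC sampler (ESS per draw is ~20× higher).
* No marker-based GRMs, no multivariate genetic correlations, no
  ascertainment correction, no multiple-testing adjustment by default (an
  optional flag is deliberately separate from the standard output).
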