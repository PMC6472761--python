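# Methods

## Model and estimation

The observational unit is the plot of a randomized-complete-block progeny
trial run in several locations.  The mixed model is

    y = X b + Z g + W i + e,

with fixed effects `b` (overall mean, location, block nested in location;
reference-level coding, so a trial with 2 locations and 3 blocks has 6
fixed-effect columns per trait), i.i.d. random progeny effects `g`,
progeny-by-location interaction effects `i`, and plot residuals `e`.
Progeny are treated as unrelated (no pedigree/kinship), which matches the
bulk-derived-family setting the generator emulates.  In multi-trait fits
the traits are stacked trait-major and every random term gets an
unstructured trait×trait covariance (`Σg ⊗ I`, `Σint ⊗ I`, `Σe ⊗ I`);
residuals are correlated across traits only within a plot and independent
across plots, the standard MTME residual assumption.  Missing cells are
handled by row deletion (observed-data likelihood) in REML and by data
augmentation in the Gibbs sampler.

### REML

Variance components are estimated by EM-REML.  Each iteration solves
Henderson's mixed-model equations (MME) at the current components and
updates each covariance block from the conditional expectation of its
effects' outer products; the residual update uses the per-plot conditional
residual moments obtained from the MME inverse.  EM guarantees a monotone
non-decreasing restricted log-likelihood, which the test suite asserts on
every fit; an Aitken-extrapolated candidate step is attempted every few
iterations and accepted only when it is PSD-valid and does not decrease
the log-likelihood.  Convergence is declared when the relative
log-likelihood change falls below `tol` (default 1e-9; the closed-form
equality tests tighten this to 1e-14 because parameter error at an EM
fixed point is roughly the square root of the log-likelihood tolerance).
Updates are projected onto the PSD cone by eigenvalue clipping; Σe is kept
strictly positive definite.  The restricted log-likelihood uses the MME
identity `-2 logL = (N−p) log 2π + log|R| + log|G| + log|M| + y'Py`;
absolute values therefore carry this constant convention and only
differences (LRT) are comparable across software.  AIC counts only
variance-covariance parameters (3 per single-trait full fit, `3·t(t+1)/2`
for a t-trait full fit); the LRT uses one degree of freedom by default, the
single-component-drop convention, with the parameter-count difference
available as an argument.

### Gibbs sampler

The Bayesian fit alternates (1) a joint multivariate-normal draw of all
fixed and random effects given the covariances (fixed effects get a normal
prior with variance 1e8), (2) imputation of masked phenotype cells from
their conditional normal given effects and Σe, and (3) conjugate
inverse-Wishart (or inverse-gamma, single trait) draws of Σg, Σint, Σe.
Default weak priors are IG(0.001, 0.001) for scalar components and
IW(scale = I, df = t+1) for matrices.  The identity scale is deliberate:
an IW prior with a near-zero scale matrix has unbounded density at
singular matrices, and in multi-trait runs the chain can enter a
near-absorbing state in which Σg collapses to rank deficiency (effects
drawn inside the deficient subspace keep the sufficient statistic
singular).  The `tr(Σ⁻¹)` term of a unit scale removes that trap while
contributing negligibly against likelihood terms of order q·Σ at trial
scale.  The default desk schedule is 20 000 iterations, 10 000 burn-in,
thinning 5; any schedule can be passed explicitly.  All draws flow from a
single seeded generator in a fixed documented order, so runs are
reproducible bit-for-bit.

Deviance for DIC is the observed-data Gaussian deviance given the fixed
effects and covariance matrices, with the random effects integrated out
analytically through the MME blocks.  This conditioning differs from
samplers that condition on the latent effects, so DIC values are
comparable between fits of this package but not with other software's
printed DIC.  Geweke's z compares the means of the first 10% and last 50%
of a chain with variances from the spectral density at zero (Bartlett
window, lag ≈ √n).  HPD intervals are the shortest sorted-sample window at
the requested probability (cross-checked against `arviz.hdi` in tests).
Posterior summaries of derived quantities (e.g. heritability) are computed
draw-wise — the transform is applied to each stored draw, then summarized —
with the mode taken as the peak of a Gaussian KDE under the Silverman-type
default bandwidth.

## Derived parameters and selection

Heritability of progeny means on a per-plot basis uses
`h² = σg²/(σg² + σint²/n + σe²/(n·r))`.  CVg and CVe are sd/grand-mean as
plain ratios, not percentages (this convention reproduces the published
table cells exactly).  REML selection accuracy is `√(1 − PEV/σg²)` — the
square root is a deliberate interpretation, since the usual accuracy
estimator is defined on the correlation scale.  Posterior accuracy
`1 − s(g)/|g|` is truncated to [0, 1] per progeny; progeny whose posterior
mean is below 1e-6 trait-sd are excluded from the reported mean and
counted.  Genetic covariances between traits come either from the
multi-trait Σg directly or, for single-trait fits, from the variance of the
plot-wise sum trait via `(var(i+j) − var(i) − var(j))/2`; correlations
outside [−1, 1] — possible only on the sum-trick route — are reported
unclipped with a flag.  Selection gain is the mean breeding value (fitted
trait mean plus BLUP deviation) of the selected set minus the overall mean;
the coincidence index `(A − C)/(M − C)` keeps `C = b·M` real-valued and may
be negative.  The additive genetic index is a weighted sum of per-trait
breeding values, by default standardized by each trait's sd so the ranking
is invariant to units, with genotypic CVs as weights; the raw-scale variant
is available because index software differs in this aggregation step and
neither variant's numeric scale is treated as canonical.

## Synthetic-trial generator

`paper_like_params()` emulates the soybean study conditions: 203 F2:4
progeny (labels cycled over 3 populations), 2 locations, 3 blocks, traits
DM/SW/SY with the published multi-trait genetic variances
(130.947, 1.8084, 10.4882), genetic correlations (−0.1107, 0.9718, −0.0217),
interaction variances (31.6741, 0.6228, 8.2995) and residual variances
(56.5234, 1.5006, 36.4419), grand means (143.45, 18.43, 20.82).
Interaction and residual cross-trait correlations are not published;
a uniform moderate 0.3 is used by default and is configurable, and this
choice is recorded in output metadata via the run manifest.  Fixed effects
default to a +5% location contrast and ±1% block offsets so the fixed part
of the model is exercised without dominating the variance.  Draws happen
in a fixed order (progeny effects, interaction effects, residuals, missing
mask) from one seeded generator.  The generator does not model population
structure or pedigree, epistasis, spatial field trend, or heterogeneous
residual variances per location — so passing tests demonstrate correct
inference under the stated model, not robustness to those real-data
features.

## Test and experiment scales

Oracles and calibration experiments are sized to run on a desk machine:
GLS/V-inverse BLUP equality on ≤10-progeny instances (1e-8), balanced-RCBD
closed-form REML equality (1e-6), single-/multi-trait reduction on
diagonal truth (1e-4 relative), genetic-variance recovery as the mean of 50
single-trait REML fits at 100 progeny (within 10% of truth), Gibbs/REML
agreement at 100 progeny (within 5% on σg²), DIC full-vs-reduced ordering
over 20 seeded 40-progeny replicates (≥90%), sum-trick vs direct
multi-trait covariance over 20 replicates (mean ratio within 10%), Geweke
calibration over 1000 i.i.d. chains, and bootstrap CI coverage over 400
bivariate-normal simulations (92–98% band).  Single-realization pipeline
checks assert only seed-robust facts; replicate-level claims live in the
experiments above.

## Known limitations

- EM-REML converges linearly; very tight parameter accuracy needs tight
  log-likelihood tolerances (handled where tests require it).
- Posterior means of weakly identified components (notably σint² in small
  multi-trait fits) can differ noticeably from REML point estimates even
  with weak priors; this is posterior skew, not sampler error, and the
  agreement claims are therefore stated for σg².
- LRT statistics can come out marginally negative when full and reduced
  fits converge to slightly different tolerances; they are clamped to zero
  with a warning.
- No factor-analytic interaction structures, heterogeneous-by-location
  residuals, narrow-sense decomposition, or economic-weight (Smith–Hazel)
  index theory.
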