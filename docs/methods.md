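# Methods

## The estimation problem

Ridge-preservation planning after molar extraction needs the root (≈ socket)
volume before surgery, but 3-D imaging (CBCT) is often not indicated, while a
2-D panoramic radiograph (PR) almost always exists. `rootvol` implements a
geometric extrapolation from the 2-D view to a volume:

1. **Elliptical surface.** Each root's projected outline is idealised as an
   ellipse with semiaxes half the root length (apex to crestal bone margin)
   and half the widest mesio-distal width perpendicular to it:
   `A_root = π·(L/2)·(W/2)`. A molar's total surface is the mesial plus the
   distal root ellipse. The widest cross-section is taken as representative
   of the whole outline regardless of its apico-coronal position — a
   deliberate idealisation, not a fitted shape.
2. **Cuboid volume.** The root solid is approximated by a prism on that
   elliptical base: `V = A · d`, with `d` the bucco-lingual depth. Molar
   sites are used because panoramic distortion is minimal there; maxillary
   molars are excluded (palatal-root overprojection breaks the two-root
   model).
3. **Projection factor.** A PR has no depth axis, so `d` is replaced by a
   cohort constant `r` calibrated on cases with CBCT ground truth:
   `r_i = V_true,i / A_PR,i`, and volumes for new teeth are estimated as
   `V̂ = A_PR · r`. `r` is dimensionally a length (mm) read as dimensionless
   because `A` is in mm² and `V` in mm³.

## Two cohort constants

The per-case factors can be pooled two ways, and the package treats both as
first-class (`ProjectionVolumeRegressor(constant=...)`):

* **mean of ratios** `mean(V_i/A_i)` — the conventionally reported summary
  (8.04 ± 1.90 on the bundled cohort; SD uses the n−1 denominator);
* **ratio of sums** `ΣV/ΣA` (≈ 7.72 on the bundled cohort) — mean-unbiased by
  construction: applying it to every surface reproduces the cohort mean
  volume exactly (asserted to machine precision in the tests).

The bundled cohort's published per-case estimated-volume column is consistent
only with a single applied constant ≈ 7.7203 (it equals ΣV/ΣA within 0.1%),
not with the reported 8.04; `validate_columns` recovers the applied constant
from the data and every report prints both constants with a discrepancy note.
The default remains `mean_of_ratios` because that is the constant users will
recognise.

The two constants differ whenever per-case factors covary with surface. The
synthetic-cohort simulations (see below) show the difference is not academic:
with measurement noise on the surfaces, the mean-of-ratios constant acquires
a positive ratio-estimator (Jensen) bias — noise in the denominator inflates
`V/A` on average — of roughly +30 mm³ out-of-sample at the default noise
level, while the ratio-of-sums constant stays within ~0.2% of unbiased. For
prediction, `ratio_of_sums` is the better default; for comparability with
reported summaries, `mean_of_ratios` is kept.

Out-of-sample error is assessed by leave-one-out (`loo_validate`, built on
sklearn's `LeaveOneOut`): refit the constant on n−1 cases, predict the
held-out case. Deriving and re-checking `r` on the same sample — the
published procedure — cannot detect overfitting; LOO can, within the limits
of a single-protocol cohort.

## Method-comparison statistics

All tests are two-sided with α = 0.05 by default.

* **Paired t** on per-case differences (scipy); zero-variance differences
  return NaN with a warning rather than an infinite statistic.
* **Pearson correlation** with the usual t-transform p-value.
* **Bland–Altman**: bias = mean(a−b), limits of agreement
  bias ± 1.96·SD(a−b) (multiplier configurable); sign convention is
  candidate (PR-derived) minus reference (CBCT truth). Plot-ready
  ((a+b)/2, a−b) pairs are exported.
* **Normality**: one-sample Kolmogorov–Smirnov against a normal with
  estimated mean/SD. With estimated parameters the plain KS p-value is
  conservative, so the **Lilliefors correction is the default**
  (statsmodels); the plain KS (`method="ks"`) is retained because it is what
  legacy point-and-click packages report and is needed to reproduce analyses
  performed with them. On the bundled cohort the two disagree on exactly one
  column (mesial PR width, which contains a 7.77 mm outlier): Lilliefors
  rejects (p = 0.027), plain KS does not (p = 0.31).
* **Power**: the paired t at effect size dz = mean(diff)/SD(diff) (Cohen's
  dz) is a one-sample t with n−1 df and noncentrality √n·dz; power is
  evaluated on the noncentral t distribution and cross-checked in the tests
  against both statsmodels and a 10⁴-replicate Monte-Carlo rejection rate.
  `required_n_paired_t` inverts the power function by integer bisection from
  a normal-approximation bracket; at tiny dz the power curve is so flat that
  the minimal n is ill-conditioned at the unit level — order of magnitude is
  the meaningful answer there.
* **Bayesian regression** (`bayes_linreg`): conjugate
  normal–inverse-gamma by default — fully explicit priors (coefficient means
  0, scales 10⁴ in residual-SD units, InvGamma(10⁻³, 10⁻³) on σ²), exact
  closed-form posterior, coefficient marginals Student-t. With vanishing
  prior precision the posterior means equal OLS to machine precision
  (asserted). An optional MCMC path (emcee, 32 walkers, 1000 burn-in,
  mandatory seed) samples the same likelihood under independent normal
  coefficient priors and reports R-hat and bulk ESS via arviz. Published
  posterior summaries from point-and-click Bayesian tools are not
  reproduction targets here because their default priors are not stated;
  the regression is judged on parameter-recovery simulations instead.

## Synthetic cohorts

`SyntheticConfig`/`generate` build cohorts truth-first so every quantity the
calibration estimates has a known generating value:

* CBCT length/width per root from a bivariate normal (correlation 0.3)
  floored at 0.5 mm; depth normal, same floor. Defaults: mesial
  11.64 ± 1.95 × 3.71 ± 0.93 mm, distal 11.09 ± 2.02 × 3.94 ± 0.81 mm
  (the reference cohort's CBCT summary), depths 7.9/7.8 ± 2.3 mm.
* True volume = shape factor × Σ_root(ellipse area × depth). The shape
  factor (default 0.88 ± 0.15) absorbs everything the cuboid idealisation
  overcounts; 0.88 is the reference cohort's mean true/cuboid volume ratio,
  and the 0.15 spread is deliberately smaller than the observed per-case
  spread (0.25) because part of that spread is measurement disagreement,
  which the generator models separately.
* PR view: lengths get an additive projection bias (default −0.7 mm, the
  observed PR−CBCT mean difference) plus Gaussian noise; widths get noise
  only (projection was found to alter lengths systematically but not
  widths). Noise SD defaults to 1.2 mm, inside the observed 0.8–1.6 mm range
  of per-root PR−CBCT difference SDs.
* Flooring is a hard `max(draw, 0.5 mm)` — total and simple, at the cost of
  a small upward bias in means when the floor is active (negligible at the
  default parameters; the column-mean tests allow for it).

Degenerate configurations make the calibration analytic: with no noise, no
bias, a fixed shape factor k and a common depth d, every per-case factor is
exactly k·d — asserted exactly in the tests. `recovery_experiment` replicates
generate→calibrate→LOO across seeds (replicate i uses seed + i) and returns
the factor and error distributions.

What the generator does **not** emulate: panoramic projection physics
(magnification varies along the arch; the bias here is a single additive
constant), tapered or curved root shapes (the shape factor is a scalar, not
shape-dependent), operator segmentation error structure, and any correlation
between measurement error and tooth size. Passing recovery tests therefore
show the estimator is correct **under the model's own assumptions**, not that
the geometric idealisation fits real anatomies — that question is answered
only by the real-cohort agreement statistics.

## Bundled reference cohort

`load_cohort()` ships a 27-molar cohort (PR and CBCT linear measurements,
CBCT segmentation volumes, and the derived printed columns). Internal
consistency is enforced by `validate_columns`: recomputed PR surfaces match
the carried surface column within 0.005 mm² and per-case factors within
0.005; one CBCT surface cell deviates by 0.08 mm² (a print rounding artefact,
flagged by the report). Per-case depths were never published, so the CBCT
cuboid column is carried as data and marked non-recomputable. Cohort summary
rows use mean ± sample SD (n−1), matching the printed tables; printed mean
rows were evidently computed on unrounded internals, so recomputed means can
differ from printed ones by up to ~0.01–0.05 in the volume columns — the
test tolerances absorb exactly that.

## Problem sizes and numerical choices

The test suite runs the full 27-case pipeline everywhere it can (it is
instantaneous); simulations use 10⁴ Monte-Carlo replicates for power
cross-checks, 100–200 replicate cohorts for recovery experiments, and
n = 2000 single cohorts for law-of-large-numbers checks — sizes chosen so
Monte-Carlo error is far below the asserted tolerances. Validation
tolerances: 0.02 for print-rounded table cells (two-decimal printing can
shift a recomputed cell by at most 0.01 per operand), machine precision
(rel 10⁻¹²) for algebraic identities. Ties and degenerate inputs: zero
variance → NaN + warning (paired t) or a raised error (correlation,
normality); `required_n` at power ≤ α returns the minimal n = 2.

## Known limitations

* The projection factor is molar-specific; nothing here transfers to
  single-rooted or three-rooted teeth.
* Calibration and validation share one acquisition protocol; LOO controls
  overfitting of the constant but not protocol-level bias.
* The elliptical/cuboid idealisation is a first-order model — the unadjusted
  cuboid overestimates true volume by ~13% on the reference cohort, which is
  precisely why the calibrated factor, not the measured depth, drives the
  PR-based estimate.
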