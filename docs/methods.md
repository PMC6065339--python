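# Methods

This note records the statistical model behind `cladodem`, the defaults
and why they are what they are, and the numerical choices a maintainer
would otherwise have to reverse-engineer.

## The study design being emulated

The unit of analysis is the cladode, the determinate-growth stem segment
(ramet) of a platyopuntia.  A campaign monitors cladodes from the bud
stage on a population of male, female and hermaphrodite plants and
records, per cladode: a size trajectory (log10 of length × width in cm),
survival to adult size, the cause of loss for casualties (removal by
large herbivores; intact death by insects/desiccation/photoinhibition;
sectioning by ranchers), post-maximum shrinkage of attached cladodes and
weight loss of manually detached ones, per-plant flowering frequency of
terminal cladodes, and rooting/budding of detached cladodes.  The
working hypothesis throughout is directional: the gender that spends
less on reproduction (male < female < hermaphrodite) should do better in
the costly vegetative traits.

## Synthetic data generator

`SimulationConfig` holds one parameter set per gender.  Defaults are the
study conditions: 29/96/31 plants (female/hermaphrodite/male), ~1.9
cladodes per plant (1 + Poisson), a 10-observation day grid (0–63 d,
weekly), flowering censuses of 47/177/72 plants, 33 detached cladodes
per gender for weight-loss tracking of which 26/24/30 remain for the
clonality outcome.

* **Growth**: per-cladode Gompertz parameters are the gender values
  jittered by a lognormal with CV 0.10 (between-cladode biological
  variation), evaluated on the day grid, plus N(0, 0.02²) measurement
  noise on the log scale.  Gender asymptotes are 2.9/2.9/3.1 log units
  (males largest, females = hermaphrodites), lag 15 d, and μ = A/27 so
  the implied exponential-phase duration A/μ is 27 days for every
  gender.
* **Survival**: Bernoulli with logit = gender intercept + 1.0 × (size −
  1.5), size being the trajectory value at a uniformly drawn observation
  day.  Intercepts (0.845/−0.647/−0.525) are calibrated so the marginal
  bud-to-adult survival frequencies land near 0.65/0.38/0.42 — the
  calibration is needed because the size covariate spends mass in the
  lag phase, so intercepts set naively from the target logits would
  undershoot.  An optional plant-level random intercept
  (`plant_intercept_sd`, default 0.0) models within-plant correlation of
  cladode fates; real data almost surely have some, but no magnitude
  estimate exists, so the default keeps the null calibration exact.
* **Loss causes**: one multinomial per gender conditional on death;
  herbivory dominates for females and hermaphrodites (0.55/0.50 vs 0.27
  for males), intact death dominates for males (0.55).
* **Shrinkage**: relative rates per day, Gaussian truncated at 0 —
  negative shrinkage would be regrowth, out of scope.  Attached means
  0.0008/0.0015/0.0022 (male/female/hermaphrodite, sd 0.0006) on
  intervals of 90–120 d; detached means 0.0015/0.0020/0.0030 (sd
  0.0006) on 71–79 d with initial weights N(1500, 300²) g.  Ordering:
  hermaphrodite > female > male.
* **Flowering**: terminal cladode count 1 + Poisson(2); flowering count
  binomial with p = 0.36/0.33/0.50.  Males highest; the female and
  hermaphrodite means both put the maturation threshold 1/mean(R/T)
  at ~3 terminal cladodes, males at ~2.
* **Clonality**: rooting Bernoulli (0.70/0.417/0.80 f/h/m) and budding
  nested within rooting (marginal 0.32/0.075/0.57) — an unrooted
  detached cladode desiccates, so budding implies rooting.
* **Seeding**: one master seed expanded into fixed-key `SeedSequence`
  substreams per table, so the bundle and each stage are byte-for-byte
  reproducible.

What the generator deliberately does not emulate: spatial structure,
plant age and size hierarchy, year-to-year environment, within-plant
correlation (by default), pollination.  Passing tests therefore show the
statistical machinery behaves as intended under the assumed generative
model, not that field data meet those assumptions.

## Growth curves

Both sigmoids are parameterized directly in (A, λ, μ), which makes the
parameters comparable across models.  Fitting is nonlinear least squares
with analytic Jacobians: an unconstrained Levenberg–Marquardt solve from
a heuristic start (A₀ = max observed; μ₀ = steepest successive slope;
λ₀ = t-intercept of that slope) plus four jittered restarts, falling
back to bounded trust-region if LM leaves the A, μ > 0 region.  λ is
left unbounded: fits must be invariant to shifting the day axis, which a
λ ≥ 0 constraint would break.  AIC is the plain `n ln(RSS/n) + 2k` with
k = 4 (three curve parameters plus the error variance); no small-sample
correction.

The model-free alternative is a GCV-penalized cubic smoothing spline
(`scipy.interpolate.make_smoothing_spline`): A is the maximum fitted
value inside the observation window, μ the maximum first derivative, λ
the t-intercept of the tangent at the steepest point; non-positive μ is
flagged degenerate.  Because the spline cannot extrapolate, its A is the
window maximum — about 7% below the true asymptote on the default grid,
one reason the parametric fits dominate model selection.

Per-parameter 90% CIs come from case-resampling the (day, log-size)
pairs (100 resamples by default); resamples with fewer than four
distinct days are counted as failures, and an interval built on > 50%
failures is flagged unreliable.  The final model choice between the
AIC-best parametric fit and the spline minimizes the summed relative CI
width Σ (hi − lo)/|estimate| over the three parameters — a scale-free
total-uncertainty criterion — with ties going to the parametric model.
Cladodes where every fit fails are excluded and logged.

The replicated simulation studies in the acceptance battery (100
pipeline replicates each) use AIC selection without the per-cladode
bootstrap; the CI-based rule is the default for single full analyses
(including `scripts/acceptance.py`).  The selection rule has no bearing
on the pooled effect directions those studies measure, and the choice
keeps each study at ~100 × 1.3 s.

## Survival and loss-cause models

The survival model is an ML binary logit (statsmodels GLM/Binomial) of
alive on gender (three-level factor, hermaphrodite reference — the
hypotheses compare unisexuals to hermaphrodites) plus the last recorded
log-size, optionally with the interaction.  Effects are tested by
likelihood-ratio chi-squares (fit with and without the effect's
columns); pairwise gender contrasts are Wald chi-squares on coefficient
differences.  The residual goodness-of-fit is a Pearson chi-square over
plant-level populations — observed vs expected deaths summed within each
plant, variance Σp(1−p) — on `n_plants − n_parameters` degrees of
freedom, honoring the nesting of cladodes within plants without random
effects.  A constant size covariate is dropped (collinear with the
intercept); degenerate responses and |coefficient| > 15 (separation)
flag the fit.  Collapsed 2×2 odds ratios add 0.5 per cell only when a
zero cell occurs, and only for reporting, never for fitting.

Loss causes are compared one cause at a time: a binary logit of (this
cause vs others) on gender among lost cladodes, pairwise Wald
chi-squares; genders with no losses are excluded with a log entry.

## Exact tests

Fisher p-values (the Boschloo ordering statistic) are computed from the
hypergeometric distribution for all (n_a+1)(n_b+1) tables at once; the
two-sided version sums outcome probabilities ≤ the observed one with the
usual 1 + 1e−7 tie tolerance.  Boschloo's p is the supremum over the
nuisance success probability π of P[Fisher p(X) ≤ Fisher p(observed)]
with X a pair of independent binomials: evaluated on a uniform
1000-point grid over [1e−6, 1 − 1e−6] (binomial pmfs accumulated in log
space), then sharpened by a bounded scalar maximization bracketing the
grid argmax.  Doubling the grid changes p by < 1e−4; the refined value
matches a 10⁴-point brute-force enumeration to 1e−6 on every table with
n_a = n_b ≤ 8 (tested).  Fisher-p ties are grouped with a 1e−12 relative
tolerance on both the fast path and the test oracles.  Grids are
memoized per (n_a, n_b, alternative), which makes simulation studies
with fixed group sizes cheap.

Two-sided Boschloo uses the two-sided Fisher p as its ordering
statistic.  The clonality battery emits, per outcome and gender pair,
the two-sided Fisher and Boschloo p plus the one-sided
(first-gender-greater) Boschloo p consumed by the directional
meta-analysis.

## Trait metrics

Rates are the plain formulas: attached shrinkage (max − min)/(days ×
max), detached (w₀ − w₁)/(days × w₀), flowering frequency R/T.
Derived demography: maturation threshold 1/mean(R/T) (minimum terminal
cladodes for one reproductive cladode, reported raw and rounded);
budding events to first reproduction = threshold / p(bud→adult);
clonality potential = p(shoot) × p(bud→adult), where p(shoot) is the
joint frequency of rooting AND budding — a new plant needs both — and
p(bud→adult) is the gender's empirical bud-to-adult survival frequency.
The pipeline estimates p(shoot) with an Agresti-style (x + 0.5)/(n + 1)
correction so the fold-advantage ratios between genders stay finite
when a 24-cladode group draws zero joint successes; even so, those
ratios are the least stable quantity the pipeline reports (a ratio of
small-sample frequencies), and single-campaign values can wander far
from their expectations.

The weighted one-way ANOVA normalizes weights to mean 1, so total
weight equals the entry count, degrees of freedom match the classical
ANOVA, and equal weights reproduce the unweighted F exactly (tested to
machine precision).  Growth parameters and attached shrinkage enter as
per-plant means weighted by cladode count.  Pairwise contrasts use the
pooled weighted residual variance; one-tailed p-values take their
direction from the trait's hypothesis sign (higher-is-better for
survival, growth rate, size, rooting, budding, flowering;
lower-is-better for lag and both shrinkages).

## Meta-analysis

Continuous traits: group SDs are recovered from the reported SEs
(s = SE√n), pooled with n − 1 weights; d = J (M₁ − M₂)/S with
J = 1 − 3/(4df − 1); sampling variance v = (n₁+n₂)/(n₁n₂) +
d²/(2(n₁+n₂)).  Dichotomous traits (survival, rooting, budding):
z = |Φ⁻¹(p_two/2)| recovers SE(ln OR) = |ln OR|/z from the trait's own
test (Wald contrast for survival, two-sided Boschloo for clonality);
the Hasselblad–Hedges factor √3/π converts to the d scale, v = 3
SE²/π².  This conversion is the standard bridge but not the only one;
analyses using a probit or arcsine link would scale |d| differently,
so pooled values are comparable within this package, not across
conversion conventions.  Signs are oriented so positive d supports the
saver-outperforms hypothesis.

d₊₊ is the 1/v-weighted mean, u the unweighted mean.  95% CIs
percentile-bootstrap the *traits* (k of them, 2000 resamples): the
synthesis is at trait level, so trait identity is the exchangeable
unit.  Known limitation: with k = 9 and uneven weights the effective
number of traits is ~5, and a percentile bootstrap of a mean at that
size runs a few points anti-conservative — in a 100-replicate
identical-gender study the d₊₊ intervals covered 0 in ~85–90 of 100
per gender pair rather than the nominal 95.  Users needing strictly
nominal coverage at small k should prefer the combined p-value, which
is calibrated by construction.

One-tailed p-values are combined with Fisher's T = −2Σln p against a
Monte-Carlo null of independent uniforms (10⁴ draws; the combined p is
the fraction of draws with T as large as observed, so 0 means "beyond
all draws", i.e. p < 1/n_mc).  Under independent uniform inputs this
matches the χ²(2k) closed form within Monte-Carlo error (tested); the
independent null makes the combination anti-conservative if the traits
are positively correlated, which is why it complements rather than
replaces the bootstrap CIs.

## Pipeline

Stages run in dependency order from one seed; fixed (data, config,
seed) reproduces every output byte for byte (tested).  `validate`
checks schemas, invariants (loss cause iff dead, strictly increasing
days, budding ⊆ rooting, one gender per plant) and cross-file
references (every growth trajectory has a survival row).  The report
is rendered from the same frames that are written to CSV, so its
numbers cannot drift from the artifacts.

## Known limitations

* The spline's A is the window maximum, biased low whenever monitoring
  stops before the plateau flattens; model selection compensates by
  preferring the parametric fits.
* Percentile bootstrap undercoverage at small trait counts (above).
* Clonality-potential fold ratios are noisy at n ≈ 24–30 per gender.
* No within-plant correlation by default, and survival clustering is
  honored only through the goodness-of-fit population structure, not
  random effects.
* The lag-phase estimate λ is biased by late first observations; the
  pipeline exposes `lag_max_initial_size` to restrict the lag analysis
  to cladodes first seen small, but no cutoff is applied by default.
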