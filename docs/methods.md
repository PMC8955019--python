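# Methods

## The task and the model

`sizebias` analyses two-alternative forced-choice (2AFC) size-discrimination
experiments in which two circular images are shown side by side and the
observer reports which looks larger. One image (the *reference*) has a fixed
size; the other (the *test*) is scaled by a signed percentage `x` of the
reference. Because the experiment may run on displays of unknown physical
size, every quantity is expressed as a percentage of the reference image —
the analysis never touches absolute lengths.

Responses are modelled with a lapse-free cumulative-Gaussian psychometric
function: the probability that the test is judged larger is

    P(x) = Φ((x − μ) / σ)

* `μ` (percent) is the **bias**, the point of subjective equality: the size
  difference at which the two images look equal. A non-zero μ means the
  depicted object's identity (a familiar ball or coin versus a neutral grey
  disc) shifts perceived size.
* `σ` (percent) is the **precision** or Weber fraction: the discrimination
  noise of the observer. Smaller is better.

The guess and lapse asymptotes are fixed at exactly 0 and 1. That is a
modelling choice, not an estimate: with 90 trials per condition there is
little power to separate a lapse parameter from a shallow slope, and fixing
the asymptotes keeps μ and σ interpretable.

Four comparison conditions are analysed: **Balls** (soccer-ball test vs.
tennis-ball reference), **Coins** (10-cent test vs. 2-euro reference), and
**Soccer** / **Tennis** (each ball vs. a grey-disc reference). With the sign
convention applied (below), a negative μ is an *assimilation* effect —
perception pulled toward the larger familiar size — and a positive μ a
*contrast* effect.

## Estimation

Per participant and condition the Bernoulli likelihood is aggregated to
binomial counts per size level and minimised as a negative log-likelihood
with probabilities clipped to `[1e-9, 1 − 1e-9]`. The optimiser is bounded
L-BFGS-B with an analytic gradient, started from the best point of a coarse
21×21 grid (μ linear over its bounds, σ geometric over its bounds); the grid
start makes the quasi-Newton step robust to the near-step-function likelihood
surfaces that very precise observers produce. Bounds are μ ∈ [−50, 50] and
σ ∈ [0.05, 100] percent — wide enough never to bind for interpretable data.
A fit that lands on a bound (e.g. constant responses) is flagged
non-converged and left for the cohort QC to remove; it is never repaired
silently.

The MLE is verified in the test suite against a brute-force grid search with
0.02-point steps, and against local perturbation probes (±0.5 in each
parameter).

### Bootstrap confidence intervals

95% percentile intervals for μ and σ come from refitting resampled data,
`B = 1000` by default. Two resampling schemes are provided:

* **parametric** (default): at each size level, binomial counts are redrawn
  from the fitted curve;
* **nonparametric**: trials are resampled with replacement (level totals
  become multinomial).

Bootstrap refits run as one vectorised pass of damped Fisher scoring on
(μ, log σ) across all replicates, started at the original estimate, with the
expected-information 2×2 system solved in closed form per replicate; rows
that stall in the interior with a non-zero gradient fall back to the bounded
quasi-Newton path. The batch fitter agrees with per-replicate direct fits to
better than 0.005 in both parameters (unit-tested) and makes a full cohort
(70 participants × 4 conditions × 1000 replicates) feasible in seconds
rather than hours. Measured coverage of the 95% μ interval at the study's
90 trials/condition is ≈ 0.96 (computed by the test suite).

### Pooled Weber fraction

Each participant's overall discrimination quality is summarised by a single
cumulative-Gaussian fit to all of their trials merged across conditions (on
the raw response axis). Mixing conditions with different μ broadens this
pooled curve, so the pooled σ̂ is an upper bound on the per-condition σ̂ —
intentional, since it is used only as a global "did they do the task at all"
screen.

## Cohort quality control

Two rules, in a fixed order, with the same 20-percentage-point yardstick
(the full −10…+10 range of presented sizes):

1. **high_weber**: pooled Weber fraction ≥ 20% — discrimination noise as
   large as the whole stimulus range.
2. **wide_ci**: any condition's 95% bias CI at least 20 points wide — the
   bias cannot be determined reliably. Applied only to survivors of rule 1,
   so a participant failing both is attributed to rule 1.

CI width is invariant under sign changes, so the rule order relative to the
sign correction is immaterial; the report reconciles counts exactly and the
whole QC step is idempotent.

**Sign convention.** In the Coins condition the nominal reference (2-euro
coin) is the *larger* familiar object, opposite to every other condition.
Coins biases and their CI endpoints are therefore negated (an involution;
σ untouched), after which negative bias = assimilation uniformly.

## Group inference

* Per-condition **medians** with two-sided Wilcoxon signed-rank tests
  against zero (medians, not means, because bias distributions are skewed).
  The Wilcoxon wrapper drops zero differences, uses the exact null for
  n ≤ 25 when tie-free and the normal approximation with continuity
  correction otherwise; it is verified against full 2^n enumeration.
* **Additivity**: per participant the *direct* bias (Balls μ) is compared
  with the *indirect* bias (Soccer μ − Tennis μ). If biases combine
  additively, the grey disc's contribution cancels in the difference and
  direct = indirect; a systematic gap would indicate super-additivity of
  the direct comparison. The group comparison is a paired Wilcoxon on the
  per-participant differences, and the group indirect value is the median
  of per-participant differences — not the difference of condition medians,
  which is not the same quantity for skewed data.
* **Weighted orthogonal (Deming) regression** between conditions. Both
  plotted variables are estimates with comparable error and identical units,
  so perpendicular distances are minimised without standardisation
  (error-variance ratio 1). The fit is the closed-form principal axis of the
  weighted covariance; with `s_xx`, `s_yy`, `s_xy` the weighted central
  second moments, `slope = (s_yy − s_xx + √((s_yy − s_xx)² + 4 s_xy²)) /
  (2 s_xy)`, intercept through the weighted centroid. Participant weights
  are `1/√(L_x² + L_y²)` with `L` the bias-CI lengths (for the
  direct-vs-indirect panel the indirect CI length combines the Soccer and
  Tennis lengths in quadrature); degenerate zero-length CIs get a capped
  weight. Slope CIs are percentile bootstrap over participants (points and
  weights resampled together, B = 1000). The closed form is verified against
  10⁴ random (slope, intercept) probes.
* **Correlations** are unweighted Pearson product-moment coefficients
  (Spearman could be argued for; Pearson is the default and the choice is
  isolated in one function).
* **Precision vs. age**: exploratory unweighted OLS of each participant's
  mean σ̂ (over the four conditions) on age, per recruitment group, with the
  95% CI half-width of the slope.

## The synthetic-observer generator

The generator exists so that every pipeline stage has known ground truth.
Per participant p (biases on the analysis scale):

    μ_Soccer = ν_S + g_p + ε,   μ_Tennis = ν_T + g_p + ε′
    μ_Balls  = μ_Soccer − μ_Tennis + η,   μ_Coins = ν_C + ε″

with `g_p ~ N(0, 2.0)` a grey-disc component shared by the two indirect
conditions (inducing their correlation), `ε ~ N(0, 1.2)` idiosyncratic, and
`η ~ N(0, 0.5)` a small additivity violation (zero makes additivity exact).
Defaults `ν_S = −5.0, ν_T = +1.5, ν_C = +1.7`; the population Balls bias is
the derived `ν_S − ν_T = −6.5`. One σ per participant, shared across
conditions, log-normal (`log-mean log 3.0`, `log-sd 0.35`), multiplied by
1.55 for the "credit" half of the cohort (emulating a less-motivated
subgroup), with an optional linear age trend. Ages are right-skewed over
17–73 (median ≈ mid-twenties). Responses are Bernoulli draws from the
observer's curve; the Coins bias is negated when simulating so that the raw
fitted value is recovered by the pipeline's sign correction.

**Planted bad observers** (defaults, all in the credit group): four with
true σ ∈ (35, 50) — caught by the pooled-Weber rule — and three that guess
at random in exactly one condition (σ effectively infinite there, their
other conditions capped at σ ≤ 3.5) — caught by the CI-width rule but not
the Weber rule. A default 70-observer cohort therefore yields 63 retained.

**Identifiability calibration.** The planted classes are only usable as
ground truth if they are separable from the good cohort, and the design
itself limits what is measurable: with levels confined to ±10%, a curve
whose central ±2σ region extends far outside the range has a bias CI that
explodes stochastically (measured: ≈1.5% of datasets at σ = 10 even with
μ = 0; ≈5% at σ = 6, μ = −9), and a pooled σ̂ of a true σ = 25 observer
falls below the 20% threshold in ≈15% of cohorts. The generator therefore
(a) redraws good observers' biases until all |μ| ≤ 8.5, (b) draws σ from
the log-normal truncated to |μ|_worst + 2σ ≤ 16 (measured residual
misclassification risk ≲ 10⁻³ per fit at the worst corner), and (c) plants
the high-Weber class at σ ≥ 35. Rejecting biases only mildly and truncating
σ — rather than rejecting the joint draw — keeps the planted bias medians
essentially undistorted (the 8.5 cap shifts the Soccer median by ≈ +0.3)
while preserving exact per-participant additivity.

**What the generator does not emulate.** Real cohorts show their largest
biases in their least precise participants; the truncation above induces,
if anything, the opposite association, and the retained synthetic cohort
spans σ ≈ 1–6.5% (mean ≈ 3.3) rather than the wider spreads real data can
show. Side biases, learning/order effects, lapses, reaction times and
screen-size heterogeneity are not modelled (sides are carried through the
trial table but never affect response probability). Passing tests therefore
demonstrate that the estimators and rules recover structure *of this kind*;
they do not certify behaviour on pathologies the generator does not
produce.

## Problem sizes and numerical choices

* Default study design: 4 conditions × 9 levels (−10…+10 by 2.5) × 2 sides
  × 5 repetitions = 360 trials/participant; default cohort 70.
* Bootstrap B = 1000 (fits and regression slopes); coverage checks in the
  test suite use 200 datasets at B = 500 — sizes chosen to estimate a 95%
  rate to a few percent.
* Likelihood clipping ε = 1e-9; bound-proximity tolerance 1e-6 of the bound
  span; Fisher scoring: ≤ 40 iterations, 12 step-halvings, convergence at
  1e-9 total parameter motion.
* Tie-break for the Deming slope when `s_xy = 0`: slope 0 if `s_xx ≥ s_yy`,
  else vertical (degenerate, signalled); all-identical points raise.
* Master-seed discipline: every stage (simulation, per-participant and
  per-condition bootstrap, regression resampling) derives its stream from
  one seed via `numpy.random.SeedSequence` spawning, so results are
  reproducible bit for bit and participants are independent of cohort
  order.

## Known limitations

* The CI-width exclusion is evaluated on bias CIs only (precision CIs are
  reported but not screened), matching its purpose of guaranteeing a
  reliable bias.
* The "range of stimuli" in both exclusion rules is read as the full 20
  percentage points between −10 and +10; a half-range reading would be
  stricter, and the threshold is a parameter for anyone who wants it.
* Percentile bootstrap intervals are first-order; no BCa correction is
  applied. Measured coverage at the default design is ≈ 0.96.
* The exact-enumeration Wilcoxon path handles ties by falling back to the
  normal approximation; for the tiny-n, heavily tied case an exact
  tie-aware permutation test would differ.
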