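# Methods

## The quantity of interest

For a test score x, conditional reliability standardises the conditional
standard error of measurement by the between-examinee score variance:

    cRel(x) = (σ² − cSEM(x)²) / σ²

The squared form is used throughout: it is the variance-ratio definition
(the proportion of score variance not attributable to conditional
error), it is dimensionally consistent, and it keeps cRel ≤ 1 with
equality exactly where cSEM = 0. cRel may be negative wherever
cSEM(x)² > σ² — typical for homogeneous cohorts mid-scale — and is
reported as computed, with a flag on the curve, rather than truncated:
truncation would hide precisely the phenomenon the comparison is about.

Both frameworks are evaluated per exam and read off at the exam's cut
score (a percent of maximum points, supplied as an input; standard
setting itself is out of scope).

## CTT route

Total scores are sums of item points (Type A items 0/1; multiple
true-false items 0/0.5/1, scored from raw ratings by the
more-than-half/all-correct rule in `score_mtf_item`). Variances use the
n−1 denominator. The conditional SEM is Lord's binomial error model,

    cSEM(X) = sqrt( X (k − X) / (k − 1) ),

evaluated on the full achievable grid X = 0 … k in scoring increments
(0.5 points when the exam contains MTF items) and reported against
percent score. The binomial model strictly assumes integer scores; with
MTF half-points the formula is applied on the points scale with
k = max_points, accepting non-integer X. The curve is symmetric about
50% with zeros at both endpoints, hence the U-shape of CTT conditional
reliability. Points on the grid actually attained by examinees are
marked in the export. Global reliability is Cronbach's alpha.

## IRT route

The measurement model is the unit-discrimination (1-PL) partial credit
model on integer categories: Type A items have one step parameter (the
Rasch difficulty), MTF items have two (the 0.5-point scores are
internally rescaled to categories {0, 1, 2}; the 0.5-point weight is
reapplied wherever points are needed, e.g. the TCC).

**Estimation.** Marginal maximum likelihood via EM on a fixed grid of
41 equally spaced quadrature nodes on [−6, 6]. The latent trait is
normal with mean fixed at 0 (identification) and standard deviation
estimated — so the separation index genuinely reflects sample
heterogeneity, which is the point of the range-restriction analysis.
The M-step is an exact per-item Newton maximisation (the expected
complete-data log-likelihood is concave in the steps) with backtracking,
and the latent-sd update only accepts improvements; the algorithm is
therefore a generalised EM and its log-likelihood trace is
non-decreasing, which the tests assert on every fit. Convergence is a
log-likelihood gain below 1e−5; non-convergence within 500 cycles is
flagged and warned, never silent. Step estimates are kept in ±8 logits:
a category that is never observed (a real occurrence — classical item
difficulties run all the way to 1.0) has a flat likelihood toward
infinity, and beyond ~8 logits the fitted probabilities are
numerically indistinguishable. An item with fewer than two observed
categories altogether is reported as unidentified by an explicit error.

**Person estimation.** Warm's weighted likelihood estimator: the score
equation plus the bias-correction term I′(θ)/(2I(θ)), where I is the
test information (sum of item category-score variances) and I′ its
derivative (sum of third central moments). In the Rasch family the
total category score is sufficient for θ, so the equation is solved
once per distinct total by safeguarded bisection on [−8, 8] (widened to
[−20, 20] if needed). WLE is finite at zero and perfect scores, where
the plain ML estimate diverges. SE(θ̂) = 1/√I(θ̂).

**Curves.** cSEM(θ) = 1/√I(θ); conditional reliability standardises by
the variance of the WLE estimates (the observed ability variance; which
variance standardises the IRT cSEM is a genuinely open choice — model
latent variance and EAP variance are alternatives — and the WLE variance
is the sample-facing one, consistent with the CTT side using observed
score variance). Each grid θ is mapped to its expected percent score
through the test characteristic curve, which is strictly increasing, so
CTT and IRT curves share the percent axis and the cut score can be
located on both. Information is computed on the θ metric; because cRel
is a ratio, the MTF point weight cancels and the curve is invariant to
the points-vs-category metric choice. Global reliability is the person
separation index (var(θ̂) − mean SE²)/var(θ̂).

## Fit diagnostics

Residuals are observed minus model-expected item scores at the WLE
point estimate of each examinee (a deliberate, test-covered choice; the
posterior-expectation alternative changes little at these test lengths).

* **Q3**: correlation of residual columns over all item pairs. Under a
  fitting model the signed statistic centres near −1/(k−1), slightly
  negative by construction; the headline summary is therefore the mean
  absolute Q3, with the signed mean alongside. Items with constant
  residuals are skipped and counted.
* **Infit/outfit**: information-weighted (Σr²/ΣW) and unweighted
  (mean r²/W) mean squares per item, expectation ≈ 1 under fit. Cells
  with numerically zero model variance are excluded and counted; an
  exam with no residual variation at all yields NaN ("not estimable")
  rather than a fabricated 1.00.
* **SRMR/SRMSR**: observed versus model-implied inter-item correlation
  matrices (implied moments by quadrature over the fitted latent
  density). SRMR is the mean absolute off-diagonal residual
  correlation, SRMSR the root-mean-square version (so SRMSR ≥ SRMR).
  These names are used inconsistently in the literature; the definitions
  here are the residual-correlation ones standard in IRT fit assessment.
* **Misfit rate**: percent of items with mean square outside
  [0.8, 1.2] by default (configurable; outfit, being outlier-sensitive,
  flags more than infit).

## Study-level analysis

Per exam: conditional reliability at the cut in both frameworks (linear
interpolation between the two flanking grid points — the grids are
dense, one point per achievable score, so the interpolation error is
negligible), the curve maximum, and the mean over *achieved* scores
(each examinee contributes the curve value at their own score/ability;
averaging over the full grid would weight unattained scores).

Across exams:

* **Theory contrast**: one-way repeated-measures ANOVA with theory as
  the within-exam factor — algebraically the squared paired t, F(1, n−1),
  with partial η² = SS_theory/(SS_theory + SS_error).
* **Influencing factors**: OLS on the stacked exam × theory table
  (2n rows): response = cRel at the cut; predictors = theory indicator
  (0 = CTT, 1 = IRT), performance range (max − min percent score), item
  count, school (a single numeric code, matching a one-row covariate
  layout; with three schools a two-dummy coding is the obvious
  alternative), MTF share (as a proportion), and the four
  theory-interactions — 9 predictors, so 2n − 10 error df.
  Standardised betas z-score the response and each predictor column,
  interactions standardised after forming the product. Significance at
  0.05.
* **Collinearity screen**: pairwise Pearson correlations among
  candidate exam-level predictors; while any retained pair exceeds
  |r| > 0.7 one member is dropped, year of study first — in these study
  designs year is essentially a proxy for the range restriction and the
  regression keeps the more proximal variable.

## Synthetic data generator

No public exam-response data exist for this setting, so the generator
is a first-class, tested component. It simulates from the same PCM used
for analysis: no generative model is implied by the analysis side, and
choosing the analysis model makes parameter recovery a meaningful
end-to-end check.

Default study conditions (all configurable): 32 exams; examinees per
exam uniform on [146, 378]; items uniform on [59, 150]; MTF share from
a normal(0.306, 0.08) truncated to [0.19, 0.533]; cut scores from a
normal(56.6, 4.7) truncated to [47.5, 70] percent. Item locations are
normal(−1.0, 1.3) on the logit scale — at ability 0 this gives a mean
classical difficulty near 0.7 with items ranging from very easy to very
hard; MTF step pairs straddle the location by a uniform [0.5, 1.5]
spread, giving ordered thresholds and a used middle category. Abilities
are standard normal; cohorts in study year y are truncated to
±(3.5 − 0.65(y − 1)) SDs, a linear homogenisation schedule that
reproduces the strong negative year/performance-range correlation with
minimal assumptions (year-1 cohorts are effectively unrestricted;
year-5 cohorts span about ±0.9 SD). Study years cycle deterministically
across exams; schools are drawn uniformly from three labels. MTF items
are generated directly at the category level; the rating-level scoring
rule (`score_mtf_item`) is provided separately for scoring raw data,
since no rating-level response model is implied by the category scoring
rule. Post-hoc eliminated items are supported only as a per-exam drop
list applied before analysis.

What the generator does **not** emulate: distractor behaviour within
Type A options, multidimensional abilities, missing responses, item
discrimination differences (the 1-PL assumption is exact in simulation,
so real data will always fit worse than these synthetics), and any
correlation between year and item count. Passing tests therefore show
that the machinery is correct and that the qualitative CTT/IRT contrast
follows from range restriction plus the two error models — not that any
particular real exam will show the same coefficients.

## Numerical choices and degenerate inputs

* Quadrature 41 nodes on [−6, 6]; EM tolerance 1e−5; latent sd searched
  in [0.1, 3]; step bound ±8 logits; WLE bisection to ~1e−17 bracket.
* Category probabilities via max-subtracted softmax; likelihoods in log
  space throughout.
* Zero total-score variance, single examinees, empty grids, constant
  residual columns and saturated cells all raise explicit errors or are
  excluded with counts — never silently imputed.
* All randomness flows from a single integer seed through spawned child
  seeds; identical (config, seed) pairs give byte-identical outputs.

## Problem sizes in the tests

The acceptance-style tests run five fully analysed 32-exam studies at
the default bands (about four minutes total), parameter recovery at
n ∈ {250, 1000} with 40 items, fit calibration at n = 2000, and an
exhaustive 0.05-step likelihood grid on two items (with coordinate
profiles plus random probes standing in for the full grid on five
items, where an exhaustive 0.05-step 5-D grid would be ~10⁹ points).

## Known limitations

* The binomial-error cSEM is applied to non-integer MTF totals; this
  mirrors practice but has no formal justification in Lord's model.
* The IRT standardising variance (WLE variance) slightly overstates
  true ability variance because estimation error is included; the
  separation index corrects for it, the curve standardisation does not.
  All alternatives share the CTT-side analogue of this issue.
* School as a single numeric code imposes an ordering on an unordered
  factor; with three balanced schools this is inconsequential for the
  theory contrasts but the coefficient itself should not be
  over-interpreted.
* EM with fixed quadrature maximises the quadrature-approximated
  likelihood; with 41 nodes on [−6, 6] the approximation error is far
  below the estimation noise at these sample sizes.
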