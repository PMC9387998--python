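# Methods

## The measurement and the model

A saccade recorded in a step-paradigm saccadometry protocol is a short
(~40–80 ms) ballistic rotation of the eye toward (prosaccade, PS) or away
from (antisaccade, AS) a peripheral target at ±10°. The package models
the angular position profile φ(t) of each saccade as the step response of
a linear second-order system with three parameters:

- **gain A** — the asymptotic plateau, in units of the normalized
  displacement (trajectories are divided by their measured amplitude
  before fitting, so A ≈ 1 with over/undershoot of the plateau expressed
  as deviations from 1; A is bounded to (0, 3]);
- **damping ratio σ** (dimensionless) — σ < 1 underdamped (overshoot and
  ringing), σ = 1 critically damped, σ > 1 overdamped (monotone
  approach). σ governs the trade-off between crossing the target early
  and minimizing retinal slip after arrival;
- **natural frequency ω₀** (rad/s) — sets the time scale; 40–80 rad/s
  gives 10° saccades lasting roughly 40–80 ms.

The three closed-form branches (underdamped / critical / overdamped) are
implemented directly; the critical branch is used only within
|σ − 1| < 10⁻⁶ because the open-branch expressions lose precision there
(continuity across the boundary is tested to sup-norm < 10⁻³ for
|σ − 1| = 10⁻³). A continuous time shift δt ∈ [−5, 5] ms absorbs the 5 ms
sampling resolution; it is a free parameter of the least-squares problem,
not a grid.

### Fitting

Each trajectory is fitted from saccade initiation (first sample whose
finite-difference speed exceeds 5 deg/s) onwards by bounded trust-region
least squares, multi-started over σ ∈ {0.5, 1.0, 1.5} ×
ω₀ ∈ {30, 60, 120} rad/s to avoid branch-local minima; the best
sum-of-squares wins, ties broken toward smaller σ. The standard error of
σ̂ comes from the linearized covariance s²(JᵀJ)⁻¹ at the optimum; its
calibration is checked by Monte-Carlo (the median reported SE lies within
a factor of two of the empirical SD of σ̂ at 0.15° sample noise). Fits
that fail or end on a parameter bound are flagged non-convergent and get
SE = ∞, so the precision filter (exclude σ-SE > 0.5) always removes them.
Noiseless recovery is exact to <1% over σ ∈ {0.5, 0.8, 1.0, 1.3} ×
ω₀ ∈ {40, 60, 80}, and recovery RMSE grows monotonically with noise.

## Preprocessing

A saccade is the first contiguous run of |velocity| > 5 deg/s (central
differences, one-sided at the ends; an optional 3-point moving average
sits behind a config flag and is off by default). Sanitization excludes
trials with latency < 100 ms or > 1000 ms, amplitude > 40°, or peak
velocity > 1000 deg/s — all strict inequalities, each rejection carrying
the first matching reason. Response types are assigned from the sign of
net displacement versus target side: PS toward the target and AS away
are correct; AS toward the target is a directional error (a reflexive
prosaccade that escaped inhibition); PS away from the target is rare,
never analyzed, and excluded outright.

## Synthetic cohorts

The generator emulates the protocol: 25 PD and 26 control participants,
fixation at 0°, targets ±10° chosen with equal probability, a
truncated-exponential foreperiod on [1.0, 2.0] s, and recording at 5 ms
from 25 ms before initiation to 20 ms after the velocity criterion
terminates the saccade. Per trial it draws latency (shifted gamma,
shift 100 ms, shape 9 — right-skewed with SD ≈ (mean−100)/3), damping
ratio and natural frequency (truncated normals, floors 0.05 and
20 rad/s), and gain (truncated normal, floor 1°), then synthesizes the
analytic step response plus Gaussian sample noise. Participants
contribute random intercepts (SDs: 20 ms latency, 0.08 damping, 5 rad/s
frequency, 0.8° gain) so the mixed models see genuine clustering.

Condition means encode the study's reported structure: antisaccades are
slower than prosaccades (+121 ms control, +147 ms PD) and more damped
(+0.06 control, +0.09 PD); AS directional errors behave like delayed
reflexive prosaccades (≈ +14 ms, damping near PS); correct antisaccades
overshoot in controls (12.31°) but not in PD (10.52°); prosaccade
latency is ~19 ms slower in PD; AS error probabilities default to 0.25
(PD) and 0.18 (control). Where the underlying study prints no value
(ω₀, trial-level SDs, between-participant SDs, error rates) the defaults
are stated choices, not estimates of any cohort.

The default measurement noise is 0.01° SD. This is a deliberate design
point: at 5 ms sampling, finite-difference velocity noise is ≈ 141 ×
noise SD in deg/s, so noise much above 0.02° would make the protocol's
own 5 deg/s detection threshold inoperable — the recording device
detects saccades on a low-noise calibrated signal. Robustness of the
*fit* to larger noise (0.05–0.3°) is studied separately on synthetic
trajectories with known onset.

What the generator does **not** emulate: blinks and head movements
(removed online by the device before export), main-sequence
amplitude–velocity coupling, vertical saccades, calibration drift, and
fatigue or session effects. Passing tests therefore demonstrate the
correctness and calibration of the analysis machinery under the model's
assumptions, not the reproduction of any particular cohort's estimates.

## Univariate inference

Each saccade-level metric is modelled as a Gaussian linear mixed model
with fixed effects of group, response type (correct PS / AS error /
correct AS) and their interaction, and a participant random intercept.
Fixed effects are tested with type-II likelihood-ratio tests: ML fits of
nested models, χ² reference with the obvious degrees of freedom. The
small-sample Kenward–Roger F-approximation is deliberately out of scope;
type-I error of the LRT group test is verified by simulation to sit in
[0.025, 0.075] at nominal 0.05 for cohorts of this size. Latency is
analyzed on the untransformed scale under the Gaussian LMM (a documented
simplification — mixed models are robust to moderate skew at these
sample sizes; a gamma-family path is not provided). Amplitude uses a
square-root transform; EMMs and CI limits are back-transformed by
squaring, which preserves ordering. Estimated marginal means are fixed-
effect predictions on the group × response-type grid from the REML fit,
with Wald 95% CIs. The contrast family is the 6 within-group response-
type pairs plus the 3 between-group same-type pairs, Bonferroni-corrected
over those 9. Singular random-intercept fits are flagged, not discarded.
The AS directional error rate (one value per participant; denominator =
correct + erroneous AS responses surviving QC) is compared between groups
with a two-tailed Mann–Whitney U (exact when small and tie-free,
otherwise normal approximation with tie and continuity corrections; the
reported U counts pairs won by the PD sample).

## Features and classifiers

Each participant is reduced to 61 named features: {median, Q1, Q3, IQR,
skewness, kurtosis} × {fit MSE, damping ratio, latency, amplitude, peak
velocity} × {PS, correct AS}, plus the AS error rate. Quantiles use
linear interpolation; skewness is adjusted Fisher–Pearson and kurtosis is
bias-corrected excess kurtosis, both reported as missing below 3–4
observations or without 3 distinct values. AS errors contribute only to
the error rate; damping and fit-MSE summaries use only fits that survive
the SE filter. Missing features are median-imputed inside each training
fold.

The logistic model is an sklearn Pipeline: median imputation →
Yeo-Johnson power transform with unit-variance scaling → residual-MI
forward selection → L2 logistic regression (unit penalty by default).
The Yeo-Johnson λ is estimated per feature by profile maximum likelihood
on a coarse-to-fine grid (step 0.01 on [−5, 5]), vectorized across
features because the transform is refitted once per leave-pair-out fold;
agreement with sklearn's `PowerTransformer` is tested to |Δλ| ≤ 0.02.
Constant training columns are mapped to zero and logged.

Forward selection estimates mutual information with equal-frequency
binning (√n bins, minimum 4; already-discrete variables pass through).
The first feature maximizes MI with the label; each later step maximizes
MI between a candidate and the current model's residual (label minus
predicted class-1 probability), which exposes features that matter only
jointly with already-selected ones — the residual retains the selected
features' information through the fitted probabilities, so e.g. the
second parent of an XOR-structured label becomes visible at step two
even though it is marginally independent of the label. After each
addition the mean stratified 5-fold CV ROC-AUC is recorded; selection
stops at the first decrease and returns the prefix with the maximum
(ties toward the shorter prefix; candidate ties toward the lowest
feature index). Because a linear model cannot convert a pure interaction
into AUC, the selection *path* is the object that demonstrates residual
recovery; the returned prefix may be shorter.

The comparison model is a 400-tree random forest (vote fractions as
probabilities, seeded). Feature importance is ranked over 75 random
subsets of 2/3 of participants: selection proportion (logistic) or mean
decrease in impurity normalized to sum 1 (forest).

## Evaluation

TLPO-CV refits the full pipeline for every unordered participant pair on
the remaining n − 2 and scores both held-out participants; the higher
score wins (ties half each). Total wins rank participants, and the
ROC-AUC of that ranking is computed through the Mann–Whitney identity
U/(n₊n₋) on midranks, which an exhaustive concordant-pair count verifies
exactly for n ≤ 10. Per-pair trainer seeds derive from the master seed
and the pair index, so results are independent of execution order. At
n = 51 this is exactly 1,275 fits of 49 participants each.

The 5×2cv combined F-test draws five stratified 50/50 splits; each fold
serves once as test, giving differences p_ij = AUC_A − AUC_B, and
F = Σp²ᵢⱼ / (2Σs²ᵢ) is referred to F(10, 5). Fold AUCs are computed from
raw predicted probabilities within the test fold. The all-zero-difference
case (identical deterministic trainers) is flagged degenerate with p = 1.
The test is conservative, markedly so when the two classifiers are fully
independent: its numerator and denominator are built from the same ten
differences and are positively dependent, so with independent
coin-flip classifiers the empirical size at nominal 0.05 is ≈ 0.017
(measured over 3,000 null runs; an iid-normal oracle for the differences
gives ≈ 0.016). Power against a real performance gap is verified
separately (oracle vs. coin-flip classifier, p < 0.05 in ≥ 90% of runs).

## Problem sizes used in the shipped studies

Simulation studies run at deliberately modest sizes chosen as desk-scale
defaults: the TLPO combinatorics and classifier evaluations use the
study's 51 participants with 20–40 trials per task; calibration suites
use 200 null mixed-model cohorts, 500 null 5×2 comparisons, 100
XOR-selection runs, and 200–500 fit-recovery replicates; the forest is
evaluated by TLPO on a 20-participant subsample (its 400-tree refits
dominate runtime). All sizes are recorded where they are used.

## Known limitations

- The damping-ratio SE is a linearization; near parameter bounds or at
  very low noise its coverage is approximate (hence the factor-of-two
  Monte-Carlo check rather than a nominal-coverage claim).
- The gamma-family mixed model for latency is not implemented; the
  Gaussian LMM on the raw scale is a documented simplification.
- The generator's AS-error latency/damping distributions are parametric
  choices consistent with the reflexive-prosaccade interpretation, not
  fitted to data.
- TLPO-CV confidence intervals are an open problem and are not reported.
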