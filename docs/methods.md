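# Methods

## Task model

The social-evaluation task is represented as a schedule of 184 trials,
one per rater, with raters partitioned into four groups whose approval
probabilities are ordered 0.87, 0.67, 0.33, 0.13 (population mean 0.50).
Two feedback modes are supported.  In `exact_frequency` (the default,
matching a pre-programmed design) each group's approval count is fixed
at round(n_group × p_k) with round-half-up, and the approvals are
assigned to raters by a seeded shuffle; realized rates therefore differ
from p_k by at most half a trial per group.  In `bernoulli` mode
feedback is drawn independently per trial, which is what the environment
simulations use.  Rater order is a seeded shuffle of all groups
interleaved (the design is not blocked).  Self-worth probes are placed
by a fixed, non-random gap pattern: the unique mixture of 2- and 3-trial
gaps solving 2x + 3y = 184, x + y = 75 (41 gaps of 2, 34 of 3),
interleaved as evenly as possible.  Probe placement is thus a design
constant; only rater order and feedback assignment vary with the seed.
Trial indices are 1-based; group indices are 0-based, ordered most- to
least-approving.

The normative fixed policy predicts "like" iff p_k > 0.5 (a tie at
exactly 0.5 is scored as "like"; accuracy is 0.5 either way), giving a
77% expected-accuracy ceiling under the default design.

## Learning models

Expected social value (ESV) per group follows the delta rule
ESV' = ESV + η(f − ESV) with binary feedback f, so each update is a
convex combination and ESV stays in [0, 1] whenever the initial values
do.  Initial ESVs of the extreme groups are free parameters; interior
groups are linearly interpolated ("equally spaced").  The choice rule is
the two-action softmax P(like) = 1/(1 + exp(−β(2·ESV − 1))); the softmax
parameterization is a convention, and fitted β values are only
comparable within this form.

Momentary self-worth is w0 + w1·S_t with S_t = γ·S_{t−1} + SPE_t and
S_0 = 0 (no pre-task prediction-error history).  The SPE index runs over
all choice trials; probes read out the running sum.  The "self-worth
update" regressor exported for event-related analyses is the
instantaneous increment w1·SPE_t at feedback; the decay of older terms
is attributed to the cue→feedback transition rather than to the update
regressor.  Rating noise is Gaussian with SD σ, treated as measurement
noise.

## Fitting

Parameters and bounds: η ∈ [0, 1], β ∈ [0, 50], V0 ∈ [0, 1]² for
choices; w0, w1 unconstrained, γ ∈ [0, 1], σ > 0 for self-worth.  The
choice likelihood is maximized by Powell search (derivative-free,
bounded) from 20 uniform seeded restarts by default, tolerance 1e-6 on
the negative log-likelihood; per-trial probabilities are floored at
1e-12 before logs.  Fits are deterministic given the restart seed.  A
fit that returns V0_lo > V0_hi is flagged, not rejected.

The self-worth model is fit sequentially after the choice model (its
fitted SPE series is the regressor input): γ is searched on a fixed
0.01-step grid, where (w0, w1) have a closed-form OLS solution and σ is
the maximum-likelihood residual SD, so the grid minimum is exact.
Ratings with zero variance yield w1 = 0 and r² = 0 by convention.
Fitting choices first and ratings second is a modeling choice; a joint
likelihood would weight the two data streams differently.

Fit indices: pseudo-r² = 1 − NLL/(n·ln 2) for choices (chance baseline
of two actions), ordinary r² for ratings, BIC = 2·NLL + k·ln n with σ
counted among the k free parameters of the Gaussian model.  Family
comparison sums BIC over subjects and picks the minimum, ties going to
the smaller family — a standard deterministic surrogate for group-level
Bayesian model selection.  The implemented family crosses learning
on/off (η ≡ 0), feedback-dependence on/off (w1 ≡ 0) and decay on/off
(γ ≡ 0).

A single 184-trial session identifies η only coarsely: at the η = 0
boundary the unconstrained estimate is approximately normal with SE
around 0.02–0.04 (β between 8 and 25), so individual boundary fits
scatter above zero even when the median sits at the boundary.
Cohort-level medians and the BIC comparison are the reliable readouts at
this scale, which is how the tests are framed.

## Synthetic cohorts

A scalar latent vulnerability factor z ~ N(μ_group, 1) (μ = +1 for the
low self-esteem group, −1 for the high group) generates both model
parameters and symptom scores.  Bounded parameters are logit-normal:
logit(param) = logit(median_group) + λ·(z − μ_group) + noise, so the
configured group medians are exact medians of the generated
distributions; β and σ are log-normal.  Group medians default to the
recruited-extremes contrast the analysis is designed around: η 0.01
(low) vs 0.05 (high), w0 0.62 vs 0.80, initial ESVs (0.70, 0.15) vs
(0.85, 0.30), w1 0.05 vs 0.03, β 8, γ 0.4, σ 0.08 vs 0.05.  Loadings
follow the vulnerability pattern (slower learning, lower baseline worth
and initial expectations, stronger feedback dependence, noisier
ratings); their magnitudes and the residual noise SDs are package
defaults chosen to give realistic single-session recovery, not published
values.  Symptom scores are base + λ·z + noise, clipped to each
instrument's range (e.g. global self-esteem 0–30, depressed mood 0–66),
with bases and loadings set so the two groups land near the
recruited-extremes questionnaire contrasts.  Setting `loading_scale=0`
decouples parameters from symptoms, which is the null configuration used
to calibrate the dimensional analysis.

Simulated agents draw choices from the softmax probabilities and report
self-worth as the kernel prediction plus Gaussian noise clipped to
[0, 1].  Clipping (rather than truncated-distribution sampling) slightly
biases ratings near the scale ends, and the fitted model ignores that
censoring — a known limitation shared with the estimator.  The generator
emulates the statistical structure the analysis assumes (one latent
dimension, logit/log-normal parameter spread, Gaussian rating noise); it
does not emulate item-level questionnaire responses, session effects,
attention lapses or choice perseveration, so passing recovery tests
demonstrates estimator correctness under the model, not robustness to
real-data misspecification.

Environment simulations shift the four group probabilities by an
additive constant to a requested mean approval (clipped to
[0.01, 0.99]), draw Bernoulli feedback with uniformly sampled groups,
and track mean |ESV − p| (averaged over groups and simulations, 500 by
default) over a 200-trial horizon.  Under these defaults, agents with
entrenched low expectations (η = 0.01, low V0) remain far from the true
probabilities in a 75%-approval world long after typical agents
(η = 0.05, higher V0) have converged, while in a 25% world their low
initial expectations are the more accurate ones at the outset.

## Vulnerability dimension

The CCA standardizes both blocks column-wise and solves via QR
decomposition of each block followed by an SVD of Qx'Qy; canonical
coefficients are returned on the standardized scale and variates have
unit sample variance.  It requires n > p + q + 1 and full column rank,
naming collinear columns otherwise.  The default parameter block is the
full fitted set {η, β, V0_hi, V0_lo, w0, w1, γ, σ} (8 variables) against
the 7 symptom instruments; the variable lists are configurable, and a
derived initial-expected-approval column (mean of the initial ESVs) is
available as an alternative to the two V0 parameters.  Each dimension is
sign-anchored so the global self-esteem coefficient is non-positive:
higher scores mean greater vulnerability.

Significance uses Rao's F approximation to Wilks' λ = Π(1 − r_i²)
(df1 = p·q for the all-dimensions test; with 7 × 8 variables and n = 61
this gives F(56, 253)), with sequential tests for higher dimensions and
a seeded permutation test as the conservative alternative — small-sample
F approximations can be liberal, though the null calibration at n = 200
is within [0.02, 0.08] at α = 0.05.  Two small-sample caveats are tested
rather than hidden: the in-sample first canonical correlation is biased
upward at n ≈ 60 (planted-factor cohorts overshoot the population
cross-block correlation), and within-group correlations of in-sample
scores inherit the same bias, sitting at the overfitting level rather
than zero under the null.

## Problem sizes and determinism

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); reruns with identical configuration are
bit-identical for the deterministic stages.  The validation suite uses
the scales at which each property is informative: 200 simulated subjects
for stochastic choice-model recovery, 60-subject cohorts per direction
for model comparison, 500 replicates for Wilks-test calibration, n = 500
with 40 replicates for planted-factor CCA recovery, and 500 simulations
per environment condition.  The acceptance script fits a 61-subject
cohort (30 low / 31 high) with 10 optimizer restarts per subject, which
reproduces the cohort-level contrasts while completing in about two
minutes.

## Known limitations

- Joint choice + self-worth estimation, hierarchical/random-effects
  fitting and posterior inference are out of scope; all fits are
  per-subject maximum likelihood.
- β is identified only jointly with the softmax form; reported values
  are not comparable across parameterizations.
- The rating model ignores the [0, 1] censoring the simulator applies.
- CCA outputs are standardized canonical coefficients, not structure
  correlations; with correlated predictors the two can differ markedly.
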