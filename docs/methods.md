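# Methods

## Task model

The task is a two-alternative SF categorization with an alternating
category boundary. `TaskConfig` holds the seven SFs (default
0.03–0.3 cycles/degree; the alternative 0.06–0.2 set used for
recording/inactivation cohorts is expressible through the same config —
no code path special-cases either set), the 90% mass on the two
block-frequent SFs, the minimum block length (60 trials), the switch rule
(≥ 70% correct on the reversing stimulus over its last 10 presentations;
0.80 for the cohorts trained to the stricter criterion), and the 15-trial
stable/switching analysis periods.

Stimuli are normalized on a log-frequency axis, linear in log-index:
`S = (log sf − log sf_rev) / (log sf_max − log sf_rev)`, giving 0 for the
reversing stimulus and ±1 at the extremes (exactly the grid
{−1, −⅔, …, 1} for an exactly log-spaced set; the printed SF values are
log-spaced only to ~0.2%, so their normalized values deviate from the
grid in the third decimal). The RL model reads the same stimuli on a
[0, 1] log axis. Both normalizations are stored per trial so both model
families read one dataset.

Period labels: the last 15 trials of a block followed by a switch are
*stable*, the first 15 of a block preceded by a switch are *switching*;
everything else (the session's opening trials, the final incomplete
block) is *other*. If a hypothetically short block makes the two windows
overlap, switching wins — the switching-period analyses are the focus,
and the real task forbids blocks under 60 trials.

## Choice models

Dynamic-DC: `p_right(t) = logistic(γ₁ S(t) − DC(t))` with the criterion
updated from the previous trial's events (±α₁ rewarded / ∓α₂ unrewarded
after reversing-stimulus trials, γ₂ S(t−1) otherwise, always on top of
the drift `(1−β) DC(t−1)`). Constraints: γ₁ ≥ 0, β ≤ 1. Variants m2–m7
clamp entries of (α₁, α₂, β, γ₁, γ₂); the fitter optimizes only free
entries, so a clamped parameter can never move.

RL: `Q_l = γ (1−S) V_l`, `Q_r = γ S V_r`, softmax choice, and the chosen
side's value updated by `α (reward − Q_chosen)` with reward ∈ {0, 1} and
α ∈ (0, 1). Initial values `V_l = V_r = 1` (a config knob; this default
makes early Q symmetric and the first rewards informative — the
convention is not dictated by the model itself). In period-restricted
fits the values reset to the initial value at each segment start by
default (`rl_reset_at_segments`), since no value trace is defined across
the excluded trials; this is likewise exposed as a knob.

### Initialization policy

Two policies unify where the latent state starts:

- `all_trials`: DC = 0 at session start and never resets; the recursion
  runs uninterrupted across block boundaries (the agent receives no
  switch cue), which is the "inherit from the previous block" convention.
- `period_reset`: the sequence is restricted to stable/switching
  segments; at each segment start DC is set to the value implied by the
  switch rule. With S = 0, `p_right = logistic(−dc)`, so a 70% correct
  rate on the reversing stimulus pins `dc = ∓ln(7/3) ≈ ∓0.847` at stable
  starts (low/high blocks) and the sign-flipped value (30% correct) at
  switching starts; an 80% criterion gives ∓ln 4. The criterion is read
  from `TaskConfig`, never hard-coded per cohort.

### Likelihood

The average negative log-likelihood (nats/trial) is computed by running
the recursion over the full ordered sequence; probabilities are clipped
at 1e−12 to keep logs finite. The recursions are JIT-compiled (numba);
the pure-Python step functions (`update_dc`, `rl_step`, `rl_update`,
`choice_prob_right`) define the reference arithmetic and the tests pin
the kernels to sequential hand evaluation on 5-trial cases.

## Simulator

`simulate_agent` runs any variant closed loop: stimuli drawn from the
block statistics (the 90% frequent mass split 0.45/0.45 between the two
frequent SFs, the 10% remainder split equally over the other five — the
split within each mass is a design choice consistent with the symmetric
block design, and configurable), choice sampled Bernoulli from the
model's `p_right`, reward by the category rule, and the block ended at
the first trial satisfying the switch rule. Criterion evaluation begins
once the block has `switch_window` reversing-stimulus trials. A safety
cap (`max_block_trials`, default 500) force-switches pathological
non-adapting agents with a warning and a counter — real subjects and the
fitted agents always meet criterion. Separate child RNG streams (block
order, stimuli, choices) are spawned from the seed, so datasets are
bit-reproducible given (params, config, seed).

`period_reset` simulation generates the analyzed segments directly: per
block, a 15-trial switching segment then a 15-trial stable segment, each
initialized at its criterion-rate DC, with no adaptive stopping rule. A
closed-loop simulation cannot reset at stable-period starts — the stable
period is defined retrospectively by the switch — so direct segment
generation is the only construction under which every segment start
carries the policy's initial value exactly. Such datasets are exempt from
the ≥60-trial block invariant (their provenance records the mode).

`apply_inactivation` scales named free parameters multiplicatively
(re-checking constraints), emulating a manipulation such as chemogenetic
silencing that reduces the history weight γ₂.

## Fitting and cross-validation

Optimization is constrained sequential quadratic programming (scipy
SLSQP) on the average NLL, best of 5 random restarts drawn uniformly
from documented boxes (α₁, α₂ ∈ [−1, 1]; β ∈ [−0.5, 0.9]; γ₁ ∈ [0.5, 10];
γ₂ ∈ [−0.5, 1.5]; RL α ∈ (0.05, 0.95), γ ∈ [0.5, 10]), objective
tolerance 1e−8, wide finite bounds enforcing the hard constraints
(γ₁ ≥ 0, β ≤ 1, RL α ∈ (0, 1); RL γ is bounded to [0, 50] since a
negative stimulus weight merely relabels the responses). Non-convergence
of every restart is flagged, never silent.

Cross-validation partitions **blocks**, not trials — the latent recursion
crosses trials within a block, so a trialwise split would be ill-posed.
Low- and high-boundary blocks are dealt round-robin into the k folds
after within-type shuffling, so per-fold type counts differ by at most
one. Both training and held-out scores run the recursion over the full
ordered sequence with a trial mask selecting whose log-likelihoods enter
the average: the recursion conditions only on observed events (stimuli,
choices, rewards — data, not fitted quantities), so held-out scoring
never includes training trials and the all-trials inheritance policy
stays well-posed during CV. The protocol default is 20 runs of 5-fold CV
(the estimator is identical at 200 runs, which `CVConfig` supports; 20
runs keeps a full recovery experiment within minutes on one CPU).
Reported quantities: the elementwise median parameter vector over all
(run, fold) fits, and `cv_likelihood = exp(mean held-out per-trial
log-likelihood)` — the geometric-mean per-trial probability of held-out
choices, a trial-count-invariant number in (0, 1) with 0.5 = chance for
binary choices (the mean held-out log-likelihood is reported alongside).

## Parameter recovery

`recover_point` simulates at known parameters and refits the same
variant; agreement is judged per free parameter as
|recovered − original| ≤ max(0.1, 15% of |original|) at the study's
simulation scale (50 blocks per type). The rule is a design choice — the
reference comparisons are scatterplots — set to sit comfortably inside
visual scatter while catching sign and scale errors. `recover_range`
sweeps one parameter over its canonical range (α₁ ∈ [−1.5, 0.8],
α₂ ∈ [−0.7, 1.5], β ∈ [−0.2, 0.9], γ₁ ∈ [1, 13], γ₂ ∈ [−0.4, 1.5]) with
the others fixed at the all-mice medians and reports the original-vs-
recovered rank correlation.

The canonical operating points are the all-mice medians: model 1
(α₁ = −0.13, α₂ = 0.13, β = 0.22, γ₁ = 3.64, γ₂ = 0.42) and model 4
(β = 0.21, γ₁ = 3.61, γ₂ = 0.36). `scripts/acceptance.py` recomputes
recovery at both points from scratch.

## Behavioral metrics

- Psychometric: binomial ML fit of
  `Ψ(x) = λ_lo + (1 − λ_lo − λ_hi) logistic((x − α)/β)` on per-SF
  right-choice counts, x in log-SF (the stimuli are log-spaced; the fitted
  threshold is then translation-equivariant in log units). Lapses bounded
  to [0, 0.5]; several deterministic starts; degenerate all-same-response
  data is flagged (boundary at ±∞), not fitted. Trials within 30 trials
  after a switch are excluded upstream (all trials, not only
  reversing-stimulus trials — the plain reading of the exclusion window).
- Reversal: correct rate for the reversing stimulus indexed by
  post-switch reversing-trial ordinal (n = 1, 2, …), pooled over all
  switches before fitting `f(n) = A (1 − e^{−n/τ}) + I` by least squares
  (first 60 ordinals). Trials-to-reverse is the analytic 50% crossing
  `n* = −τ ln(1 − (0.5 − I)/A)`, flagged undefined when the curve never
  crosses 0.5.
- Right-choice bias: over reversing-stimulus trials of a period,
  P(right | previous non-reversing low/high stimulus) minus the
  block-type-matched unconditional P(right), matched per trial (a
  conditional trial's baseline is its own block type's rate); previous
  reversing trials are excluded, matching the model's S(t−1) = 0
  convention. The difference (after-low minus after-high) is the
  history-bias statistic.

## Neural coding

ROC preference is `2 (auROC − 0.5)` with auROC computed exactly by the
rank/Mann–Whitney identity (ties 0.5 — the standard convention; the
source analysis does not state one). Sign convention: group a =
left-choice (previous-low) trials, group b = right-choice
(previous-high), so positive preference means higher firing for right
choices (previous-high stimuli). Inclusion requires ≥ 10 trials per
target class under every condition and > 0.5 spikes/s in at least one
condition.

Pseudopopulation decoding draws, per resample, 10 trials per class per
neuron without replacement (neurons were not recorded simultaneously, so
trials are resampled independently per neuron), then repeats a stratified
75/25 split 100 times: z-scoring is computed on the training split and
applied to the test split (the alternative — standardizing before the
split — leaks test statistics; the source order of operations is
unstated, so the leak-free order is adopted), classification is a linear
SVM with C = 1. Each resample contributes its repeat-averaged accuracy;
defaults are 1500 resamples (100 for sliding windows). Sliding-window
analyses use 50 ms bins stepped by 25 ms over 0–900 ms (35 bins), stamped
at bin centers.

The synthetic generator emits Poisson counts with per-neuron log-rate
`log r₀ + g_c c_i x_choice + g_h h_i x_prev`, loadings (c_i, h_i) drawn
standard-normal with correlation `coupling` — so the two ROC-preference
vectors correlate across neurons with controllable sign — and optional
per-bin structure whose tuning switches on at a configurable bin.

## What the synthetic data does and does not show

The simulator reproduces the task's block statistics, switch rule and the
fitted models' choice dynamics, and the spike generator reproduces
choice/history tuning with coupled loadings. Neither emulates real
sessions' nonstationarities (satiety, lapses of engagement), response
latencies, violation/no-response trials (every simulated trial has a
choice), session-to-session parameter drift, or the correlation structure
of simultaneously recorded neurons. Passing tests therefore certify the
estimators and analyses — identifiability, calibration, bookkeeping — on
the models' own terms, not any claim about real mice. Headline real-data
numbers (e.g. mean trials-to-reverse ≈ 6.4, mean block length ≈ 62,
the −0.71 correlation between fitted γ₂ and reversal speed, absolute
decoding accuracies) depend on the recorded datasets and are checked here
only as directions on synthetic data.

One measured caveat: for the median model-4 agent, mean trials-to-reverse
saturates near its floor (~1.6 reversing trials) once γ₂ reaches ≈ 0.4
and no longer decreases by γ₂ = 1.2. The negative association between γ₂
and reversal speed is therefore asserted on the non-saturated range
(γ₂ ∈ {0.1, 0.2, 0.4}, means ≈ 3.3 > 2.0 > 1.7 over 20 seeds of 15+15
blocks) plus a negative rank correlation including γ₂ = 0.8.

## Numerical choices and problem sizes

Probability clip 1e−12; optimizer tolerance 1e−8; nested-model NLL
comparisons allow 1e−6 of optimizer slack; the reversal crossing is
checked against a numeric root-finder to 1e−9. Model-comparison ties are
broken by listing order and flagged. Tests and analysis drivers use
desk-scale sizes chosen to keep full runs in minutes — simulations of
10–50 blocks per type, CV of 1–20 runs, decoding with tens of resamples —
while the acceptance experiments use the study-scale protocol (50+50
blocks, 20 runs of balanced 5-fold CV, 5 restarts).
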