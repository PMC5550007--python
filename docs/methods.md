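# Methods

`neurofb` simulates a closed-loop fMRI neurofeedback experiment entirely in
software. Its purpose is to let feedback schedules, hemodynamic assumptions
and learning models be explored without scanner time. This note documents
the models, the parameters that matter, the numerical choices, and what the
simulations do and do not show about real experiments.

## The simulated brain

Early visual cortex is modeled as a grid of voxels (default a 10×10×10 cube
of 3 mm voxels). 20% of voxels are orientation tuned, split equally across
the eight orientations 0°, 22.5°, …, 157.5° (2.5% each); the remaining 80%
are untuned and carry no stimulus-driven signal. A voxel preferring
orientation θ_p responds to a grating at θ with

    w(d) = (1/16)^(d/90),   d = circular distance(θ_p, θ) ∈ [0°, 90°]

— full output at the preferred orientation, decaying exponentially to 1/16
at the orthogonal orientation. Orientation space is periodic with period
180°, so patterns for θ and θ+180° are identical.

Spontaneous activity is zero-mean Gaussian with per-voxel SD σ_n, in one of
three flavors:

* **iid** — independent per voxel.
* **grf** — a Gaussian random field: white noise smoothed on the 3-D grid
  with a Gaussian kernel (FWHM 5 mm, the neuroimaging convention for
  "kernel" sizes), then re-standardized so every voxel keeps marginal SD
  σ_n exactly. The per-voxel post-smoothing SD is computed analytically
  (squared-kernel filtering of a field of ones), not by Monte Carlo.
* **orientation_mixture** — half-and-half mixture of iid Gaussian noise and
  a grating signal at an orientation drawn uniformly at random, redrawn
  independently every TR. The signal scale c is chosen in closed form so
  that on tuned voxels Var(signal) = Var(noise) = σ_n²/2; the closed form
  uses the exact first two moments of w(d) under a uniform orientation
  (the circular distance to a uniform orientation is itself uniform on
  [0°, 90°]).

The voxelwise SNR convention is tuning-curve peak (1.0) over σ_n: SNR 2
means σ_n = 0.5, SNR 10 means σ_n = 0.1. Spontaneous draws are independent
across TRs; all temporal structure in the measured signal comes from the
physiological filter. There is no measurement noise: the model isolates the
consequences of hemodynamics, not scanner physics.

## Hemodynamic filters

Four causal unit-sum filters at TR = 2 s serve both as physiological
responses h[n] and as the learner's internal models m[n]:

| kind    | weights over TR lags                              |
|---------|---------------------------------------------------|
| impulse | 1 at lag 0                                        |
| delay   | 1 at lag 3 (6 s)                                  |
| blur    | 0.2 at lags 0–4 (10-s moving average)             |
| hrf     | double-gamma sampled at lags 0–14, peak at lag 3  |

The HRF is the standard double-gamma (response gamma with shape 6, scale
1 s; undershoot shape 16, ratio 1/6), sampled every 2 s over 15 taps and
normalized by its signed sum; the small negative undershoot taps are
retained. Sampled this way the largest tap is at lag 3 (6 s) with the lag-2
tap only ~3% smaller — this near-tie matters for credit assignment (below).
Convolution is causal with zero pre-history (sessions start from rest).

## Decoding and feedback

A sparse multinomial logistic-regression classifier (L1-penalized, saga
solver) maps a voxel pattern to softmax class probabilities. Two decoders
are used: an 8-way decoder over the tuned orientations (800 training
examples, 100 per class, SNR 2) for the cognitive protocols, and a 3-way
decoder over 10°/70°/130° (210 examples, 70 per class, SNR 2) for the
automatic-learning experiments. The 8-way decoder uses inverse penalty
C = 1.0. The 3-way decoder defaults to C = 0.1, a deliberately aggressive
sparsity (~1.5–3% nonzero voxel weights) emulating the ARD-style sparse
logistic regression this pipeline is modeled on; ARD prunes far harder than
cross-validated L1. `train_classifier` also accepts `sparsity_control="cv"`
for cross-validated selection. Intercepts are fit and used consistently.

Cognitive feedback is the dot product of the 8 class probabilities with a
tuning curve circularly shifted to peak (value 1) at the target class: a
classifier fully confident one class step (22.5°) from the target scores
0.50, two steps 0.25, the orthogonal class 0.0625. The score is bounded in
(0, 1] by construction. A search succeeds when the mean score over the last
3 TRs strictly exceeds 0.85 (a tie at exactly 0.85 fails). Automatic
learning uses the raw target-class probability with no tuning curve.

Intermittent feedback stimulates the model for 3 TRs, rests 3 TRs, and
averages the decoded score over the final 3 TRs. The impulse filter is
rejected there: its response has vanished before the feedback window.

## Cognitive protocols

A pluggable agent stands in for the participant (rotation commands in
{−1, 0, +1}; both-or-neither keys leave the grating still). Continuous
search rotates at 45°/s and the per-TR stimulus orientation is the circular
mean (computed on doubled angles, since the arithmetic mean is ill-defined
across the 0/180 wrap) of the within-TR trace; the success check runs every
TR. Intermittent search selects one orientation per trial (60°/s during the
3-s selection window) and succeeds when the trial score exceeds 0.85.
Trial timings (select/stimulus/delay/feedback/wait) are 3/6/6/2/3 s
(real-time, 20 s), 3/3/3/2/2 (2×, 13 s) and 3/1/1/2/1 (6×, 8 s);
acceleration changes only bookkeeping durations, so trial scores are
bit-identical across factors at a fixed seed. The time-to-target metric for
n intermittent trials is 20·n − 5 seconds. Shipped reference agents —
jump-to-target, hold-still, greedy hill-climber, binary-search — are test
instruments, not models of human strategy; human group statistics are out
of scope.

## The automatic learner

Activity is a[n] = a_s[n] + a_c, spontaneous plus conditioned. The decoded
target probability f[n] is computed from the physiologically filtered
activity p[n] = (a ∗ h)[n], and the learning signal is the feedback change
l[n] = f[n] − f[n−1]. Credit is assigned to the memory buffer of recent
activity weighted by the internal model:

    a_c ← a_c + α · l[n] · Σ_j m[j] a[n−j]

The update accumulates: the printed single-step form would assign rather
than add, but only the accumulating form produces sustained learning (with
pure assignment the conditioned component is bounded by one step's
increment and every condition stays at chance), so accumulation is treated
as the intended reading. f[−1] is initialized to chance 1/m, which makes
α = 0 exactly stationary. a_c is neither clipped nor decayed; saturation
emerges because l → 0 as f approaches its ceiling.

Intermittent (cue-gated) learning: a_c is added to activity only during a
3-TR cue window; the trial feedback f[k] is the mean decoded output over
the following 3-TR wait window; the cue-period mean total activity is
credited once per trial with l[k] = f[k] − f[k−1]. The physiological buffer
is reset between trials — the real-time protocol's return-to-baseline wait
is what licenses this.

Learning rates follow the 1%-per-20-s convention: α = 0.01 per trial
(intermittent) or 0.001 per TR (continuous). Five simulated hours give 900
trials or 9000 TRs. The condition grid is 4 physiological filters × 4
internal models (continuous) plus 4 × cue (intermittent) = 20 conditions.

### Credit-assignment arithmetic, baselines, and one known divergence

To first order, the drift of the conditioned component under a lag-j
internal model is proportional to h[j] − h[j−1] — the learner profits
exactly when the feedback *changes* at the lag it credits. This single
quantity explains the grid: impulse–impulse and delay–delay (matched
spikes) learn strongly; blur physio + impulse internal learns (the blur
passes 20% of the change immediately) and beats blur–blur; blur physio +
delay internal is flat (equal taps, no change at lag 3); impulse physio +
hrf internal anti-learns (the HRF internal weights lag 1+, where the
impulse feedback has already reverted).

Under the HRF physiological response, the hrf and blur internal models
learn moderately and the cue schedule learns best. For the *delay* internal
model the coefficient is h[3] − h[2] ≈ +0.01 — a near-tie, because the
sampled double-gamma rises almost flat between 4 s and 6 s. With the peak
pinned at lag 3 the coefficient cannot be negative, so this implementation
yields *no* learning for hrf–delay rather than anti-learning; an HRF
realization whose sampled maximum falls at lag 2 (e.g. one dropping the
leading zero tap) flips the sign. This is the one categorical divergence
from the behavior this environment is modeled on, and it is intentional:
the filter contract (peak at 6 s = lag 3) is kept exact.

A second numerical subtlety: with a 3-class decoder the expected
target-class output under pure noise is not 1/3 but ≈ 0.37–0.44 (depending
on weight scale), because the softmax target probability is convex at the
chance point and zero-mean logit noise raises its expectation. "No
learning" therefore means flat at this measured α = 0 baseline, not at
1/m; `categorize_learning` takes the chance level as an argument.

Learning curves aggregate per-rep trajectories as the mean and the 50% CI
(25th–75th percentiles) per time point, optionally smoothed by a 200-s
moving average for display and final-value reporting. Categories:
*successful* (final 50% CI entirely above chance), *anti* (entirely below),
*none* (OLS slope of the mean curve not significant at 0.05), else
*trending*; the mean final value is reported alongside for ranking.

## Pattern-correlation analysis

The surface experiment conditions a 400-voxel model (20×20×1; 200 tuned +
200 untuned voxels, same tuning curve, σ_n = 0.5 and training recipe as the
cube) with the HRF response and the cue schedule for 900 trials, over many
independent simulated participants. Each final conditioned pattern is
correlated (Pearson) with the three noise-free orientation patterns and the
three classifier weight maps; the report is the mean of per-pattern
correlations, never the correlation of the mean pattern. Zero-variance
patterns are excluded with a logged count. Under uncorrelated Gaussian
spontaneous activity the conditioned patterns align with the *classifier
weight map* of the target far more than with the true orientation pattern,
and correlate negatively with both non-target maps (softmax punishes
non-target classes). Under the orientation-mixture noise the alignment
flips toward the *true* target pattern: learning can only reinforce
patterns that spontaneous activity actually visits. The 2-D surface
projection used for display is a seeded random bijection shared by all maps
of one participant, so it preserves every correlation.

## Problem sizes and reproducibility

All randomness flows from a master seed through named `SeedSequence`
substreams; every batch runner is bit-reproducible given its seed, and
batch runners are exactly equivalent to the single-step reference
implementations (tested by feeding both the same noise). Simulations are
vectorized across simulated participants, so full five-hour sessions are
always simulated in full; the package's standard problem sizes are 1000
reps for the two-voxel demo and the surface-correlation analysis, and 200
reps per condition for the internal-model grid. `scripts/acceptance.py`
re-runs the main experiments at these sizes and writes the resulting
numbers as JSON.

## Limitations

The generator is the study design, not a brain: no measurement noise, no
intrinsic temporal autocorrelation of spontaneous activity (all temporal
structure comes from the physiological filter), Gaussian statistics with at
most local spatial smoothing or a single random orientation signal, one
filter per session with no voxelwise HRF variability, and scripted agents
in place of human strategy. Passing tests show the closed-loop machinery
and the learning rule behave as specified under these conditions; they do
not certify effect sizes in real fMRI data.
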