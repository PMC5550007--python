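"""Reinforcement learning of spontaneous neural activity (automatic neurofeedback).

The learner holds no explicit stimulus: activity is spontaneous noise a_s[n]
plus a conditioned component a_c that accumulates whenever a change in the
decoded feedback signal l[n] = f[n] - f[n-1] credits recent activity.

* Impulse learning: the feedback is instantaneous, so the current activity
  is credited directly (a_c <- a_c + alpha * l * a).
* Continuous learning: the measured signal is the physiologically filtered
  activity p[n] = (a * h)[n]; credit is assigned to the memory buffer of
  past activity weighted by an internal temporal model m[n],
  a_c <- a_c + alpha * l * (a * m)[n].  Learning succeeds, fails or reverses
  depending on how well m matches h.
* Intermittent learning: a cue gates the conditioned activity on for 3 TRs;
  feedback is the mean decoded output over the following 3-TR wait, and the
  cue-period mean activity is credited once per trial.

The conditioned component accumulates across updates; saturation emerges as
l -> 0 when the feedback approaches its softmax ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decoder import PatternClassifier, softmax
from .hemodynamics import TemporalFilter, make_filter
from .v1_model import VoxelModel

__all__ = [
    "LearnerState",
    "TrialWindows",
    "LearningCurve",
    "step_impulse",
    "step_continuous",
    "run_intermittent_trial",
    "run_continuous_batch",
    "run_intermittent_batch",
    "run_conditioning_experiment",
    "two_voxel_classifier",
    "condition_grid",
    "CONTINUOUS_ALPHA_PER_TR",
    "INTERMITTENT_ALPHA_PER_TRIAL",
]

TR_SECONDS = 2.0
TRIAL_SECONDS = 20.0
#: learning rate of 1% per 20 s of training, expressed per update
INTERMITTENT_ALPHA_PER_TRIAL = 0.01
CONTINUOUS_ALPHA_PER_TR = 0.001


@dataclass(frozen=True)
class TrialWindows:
    """Cue and wait windows (TR indices within a trial), non-overlapping."""

    cue: tuple[int, int] = (0, 2)
    wait: tuple[int, int] = (3, 5)

    def __post_init__(self):
        if not (self.cue[0] <= self.cue[1] < self.wait[0] <= self.wait[1]):
            raise ValueError("cue window must precede the wait window")

    @property
    def n_trs(self) -> int:
        return self.wait[1] + 1


@dataclass
class LearnerState:
    """Mutable state of one simulated learner.

    ``memory`` holds the last L+1 total-activity vectors, most recent first,
    for internal-model weighting; ``f_prev`` starts at chance 1/m so the
    first learning signal is the deviation from chance and alpha=0 is exactly
    stationary.
    """

    classifier: PatternClassifier
    target_class: int
    alpha: float
    physio: TemporalFilter
    internal: TemporalFilter
    a_c: np.ndarray = None  # type: ignore[assignment]
    f_prev: float = None  # type: ignore[assignment]
    memory: np.ndarray = None  # type: ignore[assignment]
    f_history: list = field(default_factory=list)
    n: int = 0

    def __post_init__(self):
        nv = self.classifier.n_voxels
        if self.a_c is None:
            self.a_c = np.zeros(nv)
        if self.f_prev is None:
            self.f_prev = 1.0 / self.classifier.n_classes
        L = max(self.physio.L, self.internal.L)
        if self.memory is None:
            self.memory = np.zeros((L + 1, nv))

    def feedback_of(self, p: np.ndarray) -> float:
        probs = softmax(self.classifier.decision_function(p), axis=-1)[0]
        return float(probs[self.target_class])


def _push(memory: np.ndarray, a: np.ndarray) -> np.ndarray:
    out = np.roll(memory, 1, axis=0)
    out[0] = a
    return out


def step_impulse(state: LearnerState, model: VoxelModel, rng_seed=None, a_s=None) -> LearnerState:
    """One TR of impulse learning: feedback is instantaneous, current activity credited."""
    if a_s is None:
        a_s = model.sample_spontaneous(rng_seed).values
    a = a_s + state.a_c
    f = state.feedback_of(a)
    l = f - state.f_prev
    state.a_c = state.a_c + state.alpha * l * a
    state.f_prev = f
    state.f_history.append(f)
    state.memory = _push(state.memory, a)
    state.n += 1
    return state


def step_continuous(state: LearnerState, model: VoxelModel, rng_seed=None, a_s=None) -> LearnerState:
    """One TR of continuous learning through physio filter h and internal model m."""
    if a_s is None:
        a_s = model.sample_spontaneous(rng_seed).values
    a = a_s + state.a_c
    state.memory = _push(state.memory, a)
    h, m = state.physio.weights, state.internal.weights
    p = np.tensordot(h, state.memory[: len(h)], axes=1)
    f = state.feedback_of(p)
    l = f - state.f_prev
    credited = np.tensordot(m, state.memory[: len(m)], axes=1)
    state.a_c = state.a_c + state.alpha * l * credited
    state.f_prev = f
    state.f_history.append(f)
    state.n += 1
    return state


def credited_activity_expanded(memory: np.ndarray, internal: TemporalFilter) -> np.ndarray:
    """Explicit-sum form of the internal-model weighting, sum_j m[j] a[n-j].

    Algebraically identical to the buffer convolution in ``step_continuous``;
    kept as an independent route for equivalence testing.
    """
    out = np.zeros_like(memory[0])
    for j, w in enumerate(internal.weights):
        out = out + w * memory[j]
    return out


def run_intermittent_trial(
    state: LearnerState,
    model: VoxelModel,
    windows: TrialWindows = TrialWindows(),
    rng_seed=None,
    a_s=None,
) -> LearnerState:
    """One cue-gated intermittent trial.

    Conditioned activity is elicited only while the cue is on; the trial
    feedback is the mean decoded target probability over the wait window,
    and the cue-period mean total activity is credited once.  Physiological
    carryover is reset between trials (the real-time protocol's
    return-to-baseline wait justifies the reset).
    """
    n_trs = windows.n_trs
    if a_s is None:
        a_s = model.sample_spontaneous_batch(n_trs, rng_seed)
    cue = slice(windows.cue[0], windows.cue[1] + 1)
    wait = slice(windows.wait[0], windows.wait[1] + 1)
    a = np.array(a_s, dtype=float)
    a[cue] += state.a_c
    h = state.physio.weights
    p = np.zeros_like(a)
    for j, w in enumerate(h):
        if w != 0.0 and j < n_trs:
            p[j:] += w * a[: n_trs - j]
    probs = softmax(state.classifier.decision_function(p[wait]), axis=-1)
    f_trial = float(probs[:, state.target_class].mean())
    l = f_trial - state.f_prev
    a_bar = a[cue].mean(axis=0)
    state.a_c = state.a_c + state.alpha * l * a_bar
    state.f_prev = f_trial
    state.f_history.append(f_trial)
    state.n += 1
    return state


# ---------------------------------------------------------------------------
# batched runners (vectorized over simulated participants)
# ---------------------------------------------------------------------------


def run_continuous_batch(
    model: VoxelModel,
    classifier: PatternClassifier,
    target_class: int,
    physio: TemporalFilter,
    internal: TemporalFilter,
    n_trs: int,
    alpha: float = CONTINUOUS_ALPHA_PER_TR,
    n_reps: int = 1000,
    rng_seed=0,
    return_patterns: bool = False,
):
    """Continuous conditioning for ``n_reps`` independent learners at once.

    Returns feedback trajectories of shape (n_reps, n_trs) and, optionally,
    the final conditioned patterns (n_reps, n_voxels).  Identical update rule
    to ``step_continuous``; reps evolve under independent noise from a
    spawned stream per batch.
    """
    rng = np.random.default_rng(rng_seed)
    nv = model.n_voxels
    L = max(physio.L, internal.L)
    K = L + 1
    h = np.zeros(K)
    h[: physio.L + 1] = physio.weights
    m = np.zeros(K)
    m[: internal.L + 1] = internal.weights
    a_c = np.zeros((n_reps, nv))
    f_prev = np.full(n_reps, 1.0 / classifier.n_classes)
    memory = np.zeros((K, n_reps, nv))
    head = 0
    f_out = np.empty((n_reps, n_trs))
    h_perm = np.empty(K)
    m_perm = np.empty(K)
    for n in range(n_trs):
        a = model.sample_spontaneous_batch(n_reps, rng)
        a += a_c
        head = (head + 1) % K
        memory[head] = a
        # lag j lives at circular slot (head - j) % K; permute the filter
        # weights once per step instead of gathering the buffer
        idx = (head - np.arange(K)) % K
        h_perm[idx] = h
        m_perm[idx] = m
        p = np.tensordot(h_perm, memory, axes=1)
        probs = softmax(p @ classifier.W + classifier.intercepts, axis=-1)
        f = probs[:, target_class]
        l = f - f_prev
        credited = np.tensordot(m_perm, memory, axes=1)
        a_c += alpha * l[:, None] * credited
        f_prev = f
        f_out[:, n] = f
    if return_patterns:
        return f_out, a_c
    return f_out


def run_intermittent_batch(
    model: VoxelModel,
    classifier: PatternClassifier,
    target_class: int,
    physio: TemporalFilter,
    n_trials: int,
    windows: TrialWindows = TrialWindows(),
    alpha: float = INTERMITTENT_ALPHA_PER_TRIAL,
    n_reps: int = 1000,
    rng_seed=0,
    return_patterns: bool = False,
):
    """Cue-gated intermittent conditioning for ``n_reps`` learners at once.

    Returns per-trial feedback of shape (n_reps, n_trials) and optionally the
    final conditioned patterns.
    """
    rng = np.random.default_rng(rng_seed)
    nv = model.n_voxels
    n_trs = windows.n_trs
    cue = slice(windows.cue[0], windows.cue[1] + 1)
    wait = slice(windows.wait[0], windows.wait[1] + 1)
    n_cue = windows.cue[1] - windows.cue[0] + 1
    h = physio.weights
    a_c = np.zeros((n_reps, nv))
    f_prev = np.full(n_reps, 1.0 / classifier.n_classes)
    f_out = np.empty((n_reps, n_trials))
    for k in range(n_trials):
        a = model.sample_spontaneous_batch(n_trs * n_reps, rng).reshape(
            n_trs, n_reps, nv
        )
        a[cue] += a_c
        p = np.zeros((n_trs, n_reps, nv))
        for j, w in enumerate(h):
            if w != 0.0 and j < n_trs:
                p[j:] += w * a[: n_trs - j]
        probs = softmax(
            np.tensordot(p[wait], classifier.W, axes=1) + classifier.intercepts,
            axis=-1,
        )
        f = probs[:, :, target_class].mean(axis=0)
        l = f - f_prev
        a_bar = a[cue].sum(axis=0) / n_cue
        a_c += alpha * l[:, None] * a_bar
        f_prev = f
        f_out[:, k] = f
    if return_patterns:
        return f_out, a_c
    return f_out


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


@dataclass
class LearningCurve:
    """Aggregated feedback trajectory across simulated participants."""

    time_s: np.ndarray
    mean: np.ndarray
    ci25: np.ndarray
    ci75: np.ndarray
    condition: dict = field(default_factory=dict)

    def smoothed(self, window_s: float = 200.0) -> "LearningCurve":
        """Moving-average display smoothing over ``window_s`` of simulated time."""
        dt = float(self.time_s[1] - self.time_s[0]) if len(self.time_s) > 1 else 1.0
        w = max(1, int(round(window_s / dt)))
        kernel = np.full(w, 1.0 / w)

        def ma(x):
            pad = np.concatenate([np.full(w - 1, x[0]), x])
            return np.convolve(pad, kernel, mode="valid")

        return LearningCurve(
            self.time_s, ma(self.mean), ma(self.ci25), ma(self.ci75), self.condition
        )

    @property
    def final_mean(self) -> float:
        return float(self.mean[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "mean": self.mean,
                "ci25": self.ci25,
                "ci75": self.ci75,
            }
        )

    @classmethod
    def from_trajectories(cls, f: np.ndarray, dt_s: float, condition=None):
        """Aggregate (n_reps, n_points) feedback into mean and 50% CI."""
        t = (np.arange(f.shape[1]) + 1) * dt_s
        return cls(
            time_s=t,
            mean=f.mean(axis=0),
            ci25=np.percentile(f, 25, axis=0),
            ci75=np.percentile(f, 75, axis=0),
            condition=condition or {},
        )


def condition_grid() -> list[dict]:
    """The 20 simulated conditions: 16 continuous (physio x internal) + 4 cue."""
    kinds = ("impulse", "hrf", "delay", "blur")
    grid = [
        {"schedule": "continuous", "physio": p, "internal": i}
        for p in kinds
        for i in kinds
    ]
    grid += [{"schedule": "intermittent", "physio": p, "internal": "cue"} for p in kinds]
    return grid


def run_conditioning_experiment(
    model: VoxelModel,
    classifier: PatternClassifier,
    physio: str = "hrf",
    internal: str = "cue",
    schedule: str = "intermittent",
    hours: float = 5.0,
    reps: int = 1000,
    alpha_per_20s: float = 0.01,
    target_class: int = 0,
    rng_seed=0,
    return_patterns: bool = False,
):
    """Full conditioning run for one condition of the 20-condition grid.

    Five hours of training at a learning rate of 1% per 20 s translate to
    900 trials at alpha 0.01 (intermittent) or 9000 TRs at alpha 0.001
    (continuous).  Per-rep noise streams derive from the experiment seed so
    any rep is independently reproducible.
    """
    physio_f = make_filter(physio)
    if schedule == "intermittent":
        n_trials = int(round(hours * 3600.0 / TRIAL_SECONDS))
        out = run_intermittent_batch(
            model,
            classifier,
            target_class,
            physio_f,
            n_trials=n_trials,
            alpha=alpha_per_20s,
            n_reps=reps,
            rng_seed=rng_seed,
            return_patterns=return_patterns,
        )
        dt = TRIAL_SECONDS
    elif schedule == "continuous":
        if internal == "cue":
            raise ValueError("the cue internal model applies only to intermittent feedback")
        n_trs = int(round(hours * 3600.0 / TR_SECONDS))
        out = run_continuous_batch(
            model,
            classifier,
            target_class,
            physio_f,
            make_filter(internal),
            n_trs=n_trs,
            alpha=alpha_per_20s * TR_SECONDS / TRIAL_SECONDS,
            n_reps=reps,
            rng_seed=rng_seed,
            return_patterns=return_patterns,
        )
        dt = TR_SECONDS
    else:
        raise ValueError(f"unknown schedule: {schedule!r}")
    condition = {
        "physio": physio,
        "internal": internal,
        "schedule": schedule,
        "hours": hours,
        "reps": reps,
        "alpha_per_20s": alpha_per_20s,
        "target_class": target_class,
    }
    if return_patterns:
        f, patterns = out
        return LearningCurve.from_trajectories(f, dt, condition), patterns
    return LearningCurve.from_trajectories(out, dt, condition)


def two_voxel_classifier() -> PatternClassifier:
    """The two-voxel, two-class demo decoder.

    Class weight vectors are (1, -1) for the target pattern and its negation
    for the alternative, so the pattern (1, -1) yields logits (2, -2).
    """
    W = np.array([[1.0, -1.0], [-1.0, 1.0]]).T
    return PatternClassifier(
        W=W, intercepts=np.zeros(2), class_orientations=(0.0, 90.0)
    )
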