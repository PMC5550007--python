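"""Cognitive neurofeedback protocols with pluggable agents.

A (scripted) agent stands in for the human participant: it observes the
feedback history and issues rotation commands for the grating that
stimulates the V1 model.  Continuous search updates the decoded feedback
every TR while the agent rotates at 45 deg/s; intermittent search lets the
agent pick one orientation per trial (rotating at 60 deg/s during a 3-s
selection period) and scores the trial with the summarized post-stimulus
feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decoder import (
    PatternClassifier,
    SUCCESS_THRESHOLD,
    check_success,
    cognitive_feedback,
    intermittent_feedback_score,
    softmax,
)
from .hemodynamics import TemporalFilter
from .v1_model import VoxelModel, circular_orientation_distance

__all__ = [
    "TrialTiming",
    "SessionRecord",
    "AgentPolicy",
    "JumpToTargetAgent",
    "HoldStillAgent",
    "GreedyHillClimberAgent",
    "BinarySearchAgent",
    "run_continuous_search",
    "run_intermittent_search",
    "time_to_target_intermittent",
    "build_block_schedule",
    "circular_mean_orientation",
    "TIMINGS",
]

CONTINUOUS_ROTATION_DEG_S = 45.0
INTERMITTENT_ROTATION_DEG_S = 60.0
TR_SECONDS = 2.0

#: display constants recorded for completeness; rendering is not simulated
DISPLAY_CONSTANTS = {
    "grating_contrast": 0.5,
    "grating_cycles_per_deg": 0.5,
    "feedback_circle_deg_range": (0.6, 3.5),
    "threshold_circle_deg": 3.065,
    "feedback_animation_ms": 500,
    "display_hz": 60,
}


@dataclass(frozen=True)
class TrialTiming:
    """Intermittent trial phase durations in seconds."""

    acceleration: str
    select_s: float
    stimulus_s: float
    delay_s: float
    feedback_s: float
    wait_s: float

    @property
    def total_s(self) -> float:
        return self.select_s + self.stimulus_s + self.delay_s + self.feedback_s + self.wait_s


TIMINGS = {
    "realtime": TrialTiming("realtime", 3, 6, 6, 2, 3),
    "x2": TrialTiming("x2", 3, 3, 3, 2, 2),
    "x6": TrialTiming("x6", 3, 1, 1, 2, 1),
}


@dataclass
class SessionRecord:
    """Per-TR and per-trial log of one target search."""

    mode: str
    target: float
    filter_kind: str
    tr_log: list = field(default_factory=list)  # dicts: tr, orientation, probs, feedback
    trial_log: list = field(default_factory=list)
    success: bool = False
    trs_elapsed: int = 0
    n_trials: int = 0

    @property
    def time_to_target_s(self) -> float | None:
        if not self.success:
            return None
        if self.mode == "continuous":
            return TR_SECONDS * self.trs_elapsed
        return time_to_target_intermittent(self.n_trials)

    def tr_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {k: v for k, v in row.items() if k != "probs"}
                for row in self.tr_log
            ]
        )

    def trial_frame(self):
        import pandas as pd

        return pd.DataFrame(self.trial_log)


def circular_mean_orientation(angles_deg) -> float:
    """Circular mean of orientations (period 180 deg) via angle doubling."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float) * 2.0)
    mean = np.arctan2(np.sin(a).mean(), np.cos(a).mean())
    out = float(np.rad2deg(mean) / 2.0 % 180.0)
    return 0.0 if out >= 180.0 - 1e-9 else out


class AgentPolicy:
    """Interface for scripted participants.

    ``command(feedback_history, orientation, elapsed_trs)`` returns a
    rotation command in {-1, 0, +1} (counter-clockwise / hold / clockwise);
    pressing both keys and pressing neither are equivalent (0).
    ``select_orientation(trial_history)`` is used by intermittent search and
    defaults to simulating the selection period with ``command``.
    """

    def reset(self, rng: np.random.Generator) -> None:  # pragma: no cover - default
        pass

    def command(self, feedback_history, orientation, elapsed_trs) -> int:
        raise NotImplementedError

    def select_orientation(self, trial_history) -> float:
        raise NotImplementedError


class JumpToTargetAgent(AgentPolicy):
    """Oracle agent that knows the target; upper-bound test instrument."""

    def __init__(self, target: float):
        self.target = float(target)

    def command(self, feedback_history, orientation, elapsed_trs) -> int:
        d = (self.target - orientation) % 180.0
        if min(d, 180.0 - d) < 0.5:
            return 0
        return 1 if d < 90.0 else -1

    def select_orientation(self, trial_history) -> float:
        return self.target


class HoldStillAgent(AgentPolicy):
    """Never presses a key; lower-bound test instrument."""

    def command(self, feedback_history, orientation, elapsed_trs) -> int:
        return 0

    def select_orientation(self, trial_history) -> float:
        return 0.0


class GreedyHillClimberAgent(AgentPolicy):
    """Rotates in one direction, reversing whenever the feedback drops."""

    def __init__(self):
        self.direction = 1
        self._last = None

    def reset(self, rng: np.random.Generator) -> None:
        self.direction = 1 if rng.random() < 0.5 else -1
        self._last = None

    def command(self, feedback_history, orientation, elapsed_trs) -> int:
        if feedback_history:
            f = feedback_history[-1]
            if self._last is not None and f < self._last:
                self.direction = -self.direction
            self._last = f
        return self.direction


class BinarySearchAgent(AgentPolicy):
    """Intermittent-search agent that bisects over the 8 class orientations.

    Keeps the candidate set of class orientations, probes the middle of the
    best-scoring region; with noise-free feedback it reaches any target in at
    most ceil(log2(8)) + 1 trials.
    """

    def __init__(self, class_orientations=tuple(np.arange(8) * 22.5)):
        self.classes = list(class_orientations)
        self._candidates = list(self.classes)

    def reset(self, rng: np.random.Generator) -> None:
        self._candidates = list(self.classes)

    def select_orientation(self, trial_history) -> float:
        if trial_history:
            ori, score = trial_history[-1]["orientation"], trial_history[-1]["score"]
            # keep candidates whose predicted noise-free feedback is consistent
            kept = [
                c
                for c in self._candidates
                if abs((1 / 16) ** (circular_orientation_distance(c, ori) / 90.0) - score)
                < 0.125
            ]
            self._candidates = kept or list(self.classes)
        return self._candidates[len(self._candidates) // 2]

    def command(self, feedback_history, orientation, elapsed_trs) -> int:
        return 0


def _integrate_rotation(
    agent: AgentPolicy,
    orientation: float,
    feedback_history,
    elapsed_trs: int,
    duration_s: float,
    rate_deg_s: float,
    control_hz: float,
) -> tuple[float, list[float]]:
    """Piecewise-constant integration of the agent's angular velocity."""
    n_steps = max(1, int(round(duration_s * control_hz)))
    dt = duration_s / n_steps
    trace = []
    for _ in range(n_steps):
        cmd = agent.command(feedback_history, orientation, elapsed_trs)
        orientation = (orientation + np.clip(cmd, -1, 1) * rate_deg_s * dt) % 180.0
        trace.append(orientation)
    return orientation, trace


def run_continuous_search(
    agent: AgentPolicy,
    target: float,
    filt: TemporalFilter,
    model: VoxelModel,
    classifier: PatternClassifier,
    max_trs: int = 300,
    rng_seed=0,
    control_hz: float = 60.0,
    threshold: float = SUCCESS_THRESHOLD,
) -> SessionRecord:
    """One continuous-feedback target search.

    The grating starts horizontal (0 deg).  Every TR the agent's rotation is
    integrated at the control rate, the circular-mean orientation over the TR
    stimulates the model, spontaneous noise is added, the series is filtered,
    decoded, and scored; the search succeeds when the mean score over the
    last 3 TRs exceeds the threshold.
    """
    rng = np.random.default_rng(rng_seed)
    agent.reset(rng)
    record = SessionRecord(mode="continuous", target=target, filter_kind=filt.kind)
    noise = model.sample_spontaneous_batch(max_trs, rng)
    orientation = 0.0
    feedback_history: list[float] = []
    buffer = np.zeros((filt.L + 1, model.n_voxels))
    for tr in range(max_trs):
        orientation, trace = _integrate_rotation(
            agent, orientation, feedback_history, tr, TR_SECONDS,
            CONTINUOUS_ROTATION_DEG_S, control_hz,
        )
        theta = circular_mean_orientation(trace)
        a = model.stimulus_pattern(theta).values + noise[tr]
        buffer = np.roll(buffer, 1, axis=0)
        buffer[0] = a
        p = np.tensordot(filt.weights, buffer, axes=1)
        probs = softmax(classifier.decision_function(p), axis=-1)[0]
        score = cognitive_feedback(probs, target, classifier.class_orientations)
        feedback_history.append(float(score))
        record.tr_log.append(
            {"tr": tr, "orientation": theta, "probs": probs, "feedback": float(score)}
        )
        record.trs_elapsed = tr + 1
        if check_success(feedback_history, threshold):
            record.success = True
            break
    return record


def run_intermittent_search(
    agent: AgentPolicy,
    target: float,
    filt: TemporalFilter,
    model: VoxelModel,
    classifier: PatternClassifier,
    timing: TrialTiming = TIMINGS["realtime"],
    max_trials: int = 30,
    rng_seed=0,
    threshold: float = SUCCESS_THRESHOLD,
) -> SessionRecord:
    """One intermittent-feedback target search.

    The agent selects an orientation each trial; the trial score is the
    summarized post-stimulus feedback and the search succeeds when it
    exceeds the threshold.  Acceleration factors change only the bookkeeping
    durations: the feedback computation always follows the real-time
    protocol, so trial scores are identical across timings at a fixed seed.
    """
    if filt.kind == "impulse":
        raise ValueError("intermittent search is undefined for the impulse filter")
    ss = np.random.SeedSequence(rng_seed) if not isinstance(
        rng_seed, np.random.SeedSequence
    ) else rng_seed
    agent_seed, score_seed = ss.spawn(2)
    agent.reset(np.random.default_rng(agent_seed))
    record = SessionRecord(mode="intermittent", target=target, filter_kind=filt.kind)
    trial_history: list[dict] = []
    score_streams = score_seed.spawn(max_trials)
    for k in range(max_trials):
        orientation = float(agent.select_orientation(trial_history)) % 180.0
        score = intermittent_feedback_score(
            model, classifier, filt, orientation, target, score_streams[k]
        )
        success = score > threshold
        row = {
            "trial": k,
            "orientation": orientation,
            "score": score,
            "success": success,
            "target": target,
            "filter": filt.kind,
            "acceleration": timing.acceleration,
            "trial_duration_s": timing.total_s,
        }
        trial_history.append(row)
        record.trial_log.append(row)
        record.n_trials = k + 1
        if success:
            record.success = True
            break
    return record


def time_to_target_intermittent(n_trials: int) -> float:
    """Real-time-equivalent search duration: 20 s per trial minus a 5 s credit.

    The credit removes the 3 s wait absent before the first trial and the
    2 s of the final feedback period after the score is known.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return 20.0 * n_trials - 5.0


def build_block_schedule(mode: str, rng_seed=0) -> list[dict]:
    """Target/filter schedule for a full session.

    Continuous: an impulse familiarization block first, then the hrf/blur/
    delay blocks in counterbalanced (seeded) order; each block has 3 visible
    training targets (45, 90, 135 deg) then 14 hidden targets, two per
    orientation.  Intermittent: 7 blocks of 9 targets (all timings use the
    same hrf/delay/blur assignment machinery upstream), orientations as
    balanced as a 63-target schedule allows.
    """
    rng = np.random.default_rng(rng_seed)
    orientations = np.arange(8) * 22.5
    schedule = []
    if mode == "continuous":
        filters = ["impulse"] + list(rng.permutation(["hrf", "blur", "delay"]))
        for block, fk in enumerate(filters):
            for t in (45.0, 90.0, 135.0):
                schedule.append(
                    {"block": block, "filter": fk, "target": t, "visible": True}
                )
            # 14 hidden targets at most two per orientation (14 cannot hold
            # two of each of the 8 orientations; one is dropped per block)
            kept = np.delete(orientations, rng.integers(8))
            hidden = np.repeat(kept, 2)
            rng.shuffle(hidden)
            for t in hidden:
                schedule.append(
                    {"block": block, "filter": fk, "target": float(t), "visible": False}
                )
    elif mode == "intermittent":
        counts = np.full(8, 8)
        counts[rng.integers(8)] = 7  # 63 targets cannot split evenly over 8
        targets = np.repeat(orientations, counts)
        rng.shuffle(targets)
        for i, t in enumerate(targets):
            schedule.append(
                {
                    "block": i // 9,
                    "filter": None,
                    "target": float(t),
                    "visible": i < 3,
                }
            )
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return schedule
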