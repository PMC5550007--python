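"""Pattern decoding and feedback-signal computation.

A sparse (L1-penalized) multinomial logistic regression classifier maps a
voxel pattern to softmax class probabilities.  Cognitive feedback is the dot
product of those probabilities with a decaying-exponential tuning curve
circularly shifted to peak at the target orientation, so that near-misses
still produce graded feedback (a grating one class step, 22.5 deg, from the
target scores 0.50; two steps, 45 deg, scores 0.25).  Automatic-learning
feedback is the raw target-class probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

from .hemodynamics import TemporalFilter, apply_filter
from .v1_model import VoxelModel, circular_orientation_distance, tuning_response

__all__ = [
    "PatternClassifier",
    "train_classifier",
    "predict_proba",
    "softmax",
    "feedback_tuning_curve",
    "cognitive_feedback",
    "check_success",
    "intermittent_feedback_score",
    "SUCCESS_THRESHOLD",
]

SUCCESS_THRESHOLD = 0.85
COGNITIVE_ORIENTATIONS = tuple(np.arange(8) * 22.5)
AUTOMATIC_ORIENTATIONS = (10.0, 70.0, 130.0)

#: default inverse L1 penalty for the 3-way automatic decoder; aggressive
#: sparsity emulating ARD-style sparse logistic regression (~15 active voxels
#: per class on the 1000-voxel model)
AUTOMATIC_SPARSITY = 0.1


def softmax(logits, axis=-1):
    z = np.asarray(logits, dtype=float)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class PatternClassifier:
    """Multinomial softmax decoder: probs = softmax(W^T a + b).

    W is (n_voxels, n_classes); one weight map per class orientation.
    """

    W: np.ndarray
    intercepts: np.ndarray
    class_orientations: tuple[float, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if self.W.shape[1] != len(self.class_orientations):
            raise ValueError("W must have one column per class orientation")
        if self.intercepts.shape != (self.W.shape[1],):
            raise ValueError("intercepts must have one entry per class")

    @property
    def n_classes(self) -> int:
        return self.W.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.W.shape[0]

    def class_index(self, orientation: float) -> int:
        d = circular_orientation_distance(np.asarray(self.class_orientations), orientation)
        i = int(np.argmin(d))
        if d[i] > 1e-9:
            raise ValueError(f"{orientation} deg is not a class orientation")
        return i

    def weight_map(self, orientation: float) -> np.ndarray:
        return self.W[:, self.class_index(orientation)]

    def decision_function(self, patterns) -> np.ndarray:
        a = np.atleast_2d(np.asarray(patterns, dtype=float))
        if a.shape[-1] != self.n_voxels:
            raise ValueError(
                f"pattern has {a.shape[-1]} voxels, classifier expects {self.n_voxels}"
            )
        return a @ self.W + self.intercepts

    def to_frame(self):
        import pandas as pd

        rows = []
        for ci, ori in enumerate(self.class_orientations):
            rows.append(
                pd.DataFrame(
                    {
                        "class_orientation": ori,
                        "voxel_index": np.arange(self.n_voxels),
                        "weight": self.W[:, ci],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def train_classifier(
    patterns,
    labels,
    class_orientations,
    sparsity_control: float | str = 1.0,
    rng_seed: int = 0,
    max_iter: int = 2000,
) -> PatternClassifier:
    """Fit the sparse multinomial logistic decoder.

    ``sparsity_control`` is the inverse L1 penalty strength C, or "cv" to
    select C by cross-validation on the training set.  L1 drives a subset of
    voxel weights exactly to zero, mirroring sparse logistic regression as
    used for fMRI orientation decoding.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    if len(np.unique(labels)) != len(class_orientations):
        raise ValueError("labels must cover every class orientation")
    common = dict(
        solver="saga",
        max_iter=max_iter,
        tol=1e-4,
        random_state=int(rng_seed) % (2**31),
    )
    if sparsity_control == "cv":
        clf = LogisticRegressionCV(
            Cs=np.logspace(-2, 2, 5), cv=3, l1_ratios=[1.0], **common
        )
    else:
        clf = LogisticRegression(C=float(sparsity_control), l1_ratio=1.0, **common)
    clf.fit(np.asarray(patterns, dtype=float), labels)
    order = np.argsort(clf.classes_)
    W = clf.coef_[order].T
    b = clf.intercept_[order]
    return PatternClassifier(
        W=W,
        intercepts=b,
        class_orientations=tuple(float(o) for o in class_orientations),
        meta={"sparsity_control": sparsity_control, "rng_seed": rng_seed},
    )


def predict_proba(classifier: PatternClassifier, pattern) -> np.ndarray:
    """Softmax class probabilities for one pattern (or a batch)."""
    logits = classifier.decision_function(pattern)
    p = softmax(logits, axis=-1)
    return p[0] if np.asarray(pattern).ndim == 1 else p


def feedback_tuning_curve(class_orientations, target: float) -> np.ndarray:
    """Decaying-exponential weights over classes, peak 1 at the target class."""
    oris = np.asarray(class_orientations, dtype=float)
    d = circular_orientation_distance(oris, target)
    if d.min() > 1e-9:
        raise ValueError(f"target {target} deg is not one of the class orientations")
    return tuning_response(oris, target)


def cognitive_feedback(probs, target: float, class_orientations=COGNITIVE_ORIENTATIONS):
    """Tuning-curve-weighted feedback score in (0, 1].

    The dot product of the classifier probability vector with the
    target-shifted tuning curve; bounded by construction so it can be shown
    on a thermometer display without rescaling.
    """
    probs = np.asarray(probs, dtype=float)
    curve = feedback_tuning_curve(class_orientations, target)
    return probs @ curve


def check_success(feedback_history, threshold: float = SUCCESS_THRESHOLD) -> bool:
    """Target reached iff the mean of the last 3 TR scores strictly exceeds threshold."""
    h = np.asarray(feedback_history, dtype=float)
    if h.size < 3:
        return False
    return bool(np.mean(h[-3:]) > threshold)


def intermittent_feedback_score(
    model: VoxelModel,
    classifier: PatternClassifier,
    filt: TemporalFilter,
    orientation: float,
    target: float,
    rng_seed,
) -> float:
    """Summarized feedback for one intermittent trial.

    The model is stimulated at ``orientation`` for 3 TRs, then rests for
    3 TRs; after physiological filtering, the cognitive feedback score is
    averaged over the final 3 TRs (the wait period catches the delayed
    response).  Not defined for the impulse filter, whose response has
    already vanished by the wait period.
    """
    if filt.kind == "impulse":
        raise ValueError(
            "intermittent feedback is undefined for the impulse filter: the "
            "instantaneous response is not captured by the post-stimulus "
            "feedback-calculation window"
        )
    stim = model.stimulus_pattern(orientation).values
    series = np.zeros((6, model.n_voxels))
    series[:3] = stim
    series += model.sample_spontaneous_batch(6, rng_seed)
    p = apply_filter(series, filt)
    probs = softmax(classifier.decision_function(p), axis=-1)
    scores = [
        cognitive_feedback(probs[n], target, classifier.class_orientations)
        for n in range(3, 6)
    ]
    return float(np.mean(scores))
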