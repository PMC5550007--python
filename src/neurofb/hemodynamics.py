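"""Causal temporal filters linking neural activity to the measured signal.

Four candidate physiological responses, all sampled at the scan TR (2 s) and
normalized to unit weight sum:

* ``impulse`` — the identity; activity is measured instantaneously.
* ``hrf`` — the canonical double-gamma BOLD response over 15 TRs, peaking at
  lag 3 (6 s).
* ``delay`` — a pure 3-TR (6 s) lag, the delay-to-peak of the HRF in
  isolation.
* ``blur`` — a 5-TR (10 s) moving average, the blur of the HRF in isolation.

The same objects serve as internal credit-assignment models m[n] in the
automatic learner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma

__all__ = ["TemporalFilter", "make_filter", "apply_filter", "FILTER_KINDS"]

FILTER_KINDS = ("impulse", "hrf", "delay", "blur")

# double-gamma parameterization: response peak at 6 s, undershoot at 16 s,
# undershoot amplitude 1/6 of the response
_HRF_RESPONSE_SHAPE = 6.0
_HRF_UNDERSHOOT_SHAPE = 16.0
_HRF_UNDERSHOOT_RATIO = 1.0 / 6.0
_HRF_N_TAPS = 15


@dataclass(frozen=True)
class TemporalFilter:
    """Normalized causal filter weights over TR lags 0..L."""

    kind: str
    tr_seconds: float
    weights: np.ndarray = field(repr=False)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("filter weights must sum to 1")

    @property
    def L(self) -> int:
        """Maximum lag in TRs."""
        return len(self.weights) - 1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"lag_TR": np.arange(len(self.weights)), "weight": self.weights}
        )

    @classmethod
    def from_frame(cls, frame, kind: str = "custom", tr_seconds: float = 2.0):
        frame = frame.sort_values("lag_TR")
        lags = frame["lag_TR"].to_numpy()
        if not np.array_equal(lags, np.arange(len(lags))):
            raise ValueError("lags must be contiguous from 0")
        return cls(kind=kind, tr_seconds=tr_seconds, weights=frame["weight"].to_numpy())


def _double_gamma_weights(tr_seconds: float) -> np.ndarray:
    t = np.arange(_HRF_N_TAPS) * tr_seconds
    h = gamma.pdf(t, _HRF_RESPONSE_SHAPE) - _HRF_UNDERSHOOT_RATIO * gamma.pdf(
        t, _HRF_UNDERSHOOT_SHAPE
    )
    # normalize by the signed sum; small negative undershoot taps are retained
    return h / h.sum()


def make_filter(kind: str, tr_seconds: float = 2.0) -> TemporalFilter:
    """Build one of the four named filters at the given TR."""
    if kind == "impulse":
        w = np.array([1.0])
    elif kind == "delay":
        w = np.array([0.0, 0.0, 0.0, 1.0])
    elif kind == "blur":
        w = np.full(5, 0.2)
    elif kind == "hrf":
        w = _double_gamma_weights(tr_seconds)
    else:
        raise ValueError(f"unknown filter kind: {kind!r}")
    return TemporalFilter(kind=kind, tr_seconds=tr_seconds, weights=w)


def apply_filter(series, filt: TemporalFilter, tr_seconds: float | None = None):
    """Causal convolution of a TR-indexed series with a temporal filter.

    ``series`` has time on the first axis; additional axes (e.g. voxels) are
    filtered independently.  Pre-history before t=0 is taken as zero.
    """
    if tr_seconds is not None and not np.isclose(tr_seconds, filt.tr_seconds):
        raise ValueError(
            f"series TR {tr_seconds}s does not match filter TR {filt.tr_seconds}s"
        )
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    out = np.zeros_like(series)
    for j, w in enumerate(filt.weights):
        if w != 0.0 and j < n:
            out[j:] += w * series[: n - j]
    return out
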