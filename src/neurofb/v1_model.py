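"""Simulated V1 voxel model.

A rectangular grid of voxels, a fixed fraction of which are tuned to one of
eight grating orientations.  The tuning curve is a decaying exponential with
full response at the preferred orientation and 1/16 of it at the orthogonal
orientation.  Spontaneous activity is Gaussian, either independent per voxel
("iid"), spatially smoothed on the 3-D grid ("grf"), or a half-and-half
mixture of independent noise and a randomly oriented grating signal
("orientation_mixture").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d, gaussian_filter1d

__all__ = [
    "VoxelModel",
    "ActivityPattern",
    "circular_orientation_distance",
    "tuning_response",
    "DEFAULT_ORIENTATIONS",
]

DEFAULT_ORIENTATIONS = tuple(np.arange(8) * 22.5)

#: ratio of the tuning-curve response at the orthogonal orientation to the peak
ORTHOGONAL_RATIO = 1.0 / 16.0

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def circular_orientation_distance(theta1, theta2):
    """Angular distance between two grating orientations, in degrees.

    Orientation space is periodic with period 180 deg, so the distance is
    folded into [0, 90].
    """
    d = np.abs(np.asarray(theta1, dtype=float) - np.asarray(theta2, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)


def tuning_response(preferred, stimulus):
    """Exponential tuning curve: 1 at the preferred orientation, 1/16 at 90 deg."""
    d = circular_orientation_distance(preferred, stimulus)
    return ORTHOGONAL_RATIO ** (d / 90.0)


def _mixture_signal_moments():
    """Mean and variance of the tuning response to a uniformly random orientation.

    The circular distance between a fixed preferred orientation and a uniform
    orientation is itself uniform on [0, 90], so both moments have closed
    forms for the exponential curve w(d) = (1/16)**(d/90).
    """
    k = np.log(1.0 / ORTHOGONAL_RATIO) / 90.0  # decay rate per degree
    mean = (1.0 - ORTHOGONAL_RATIO) / (90.0 * k)
    second = (1.0 - ORTHOGONAL_RATIO**2) / (180.0 * k)
    return mean, second - mean**2


@dataclass
class ActivityPattern:
    """Per-voxel activity at a single TR."""

    values: np.ndarray
    timestamp: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class VoxelModel:
    """Geometry, orientation tunings and noise parameters of the simulated brain.

    Parameters
    ----------
    grid_shape
        Voxels per axis; the default 10x10x10 cube gives 1000 voxels.
    voxel_size_mm
        Edge length of a voxel in millimetres.
    tuned_orientations
        Preferred orientations in degrees on [0, 180).
    fraction_tuned
        Fraction of all voxels carrying orientation tuning, split equally
        across ``tuned_orientations``.
    noise_sigma
        Marginal standard deviation of spontaneous activity per voxel.
    noise_kind
        "iid", "grf" (spatially smoothed Gaussian) or "orientation_mixture".
    grf_kernel_mm
        FWHM of the Gaussian smoothing kernel for the "grf" noise model.
    """

    grid_shape: tuple[int, int, int] = (10, 10, 10)
    voxel_size_mm: float = 3.0
    tuned_orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS
    fraction_tuned: float = 0.20
    noise_sigma: float = 0.5
    noise_kind: str = "grf"
    grf_kernel_mm: float = 5.0
    assignment_seed: int = 0
    tuning_assignment: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_kind not in ("iid", "grf", "orientation_mixture"):
            raise ValueError(f"unknown noise_kind: {self.noise_kind!r}")
        oris = np.asarray(self.tuned_orientations, dtype=float) % 180.0
        if len(np.unique(oris)) != len(oris):
            raise ValueError("tuned_orientations must be distinct modulo 180")
        self.tuned_orientations = tuple(oris)
        if self.tuning_assignment is None:
            self.tuning_assignment = self._default_assignment()
        self.tuning_assignment = np.asarray(self.tuning_assignment)
        if self.tuning_assignment.shape != (self.n_voxels,):
            raise ValueError("tuning_assignment must have one label per voxel")
        self._preferred = np.full(self.n_voxels, np.nan)
        tuned = self.tuning_assignment >= 0
        self._preferred[tuned] = oris[self.tuning_assignment[tuned]]
        if self.noise_kind == "grf":
            self._grf_std_map = self._smoothing_std_map()

    # -- construction -------------------------------------------------------

    def _default_assignment(self) -> np.ndarray:
        """Assign fraction_tuned of voxels equally to the tuned orientations.

        Labels are orientation indices; -1 marks untuned voxels.  Placement on
        the grid is a seeded permutation (voxel order is row-major).
        """
        n = self.n_voxels
        n_tuned = int(round(self.fraction_tuned * n))
        k = len(self.tuned_orientations)
        per = np.full(k, n_tuned // k)
        per[: n_tuned - per.sum()] += 1  # distribute remainder, counts within +/-1
        labels = np.full(n, -1, dtype=int)
        labels[:n_tuned] = np.repeat(np.arange(k), per)
        rng = np.random.default_rng(self.assignment_seed)
        return rng.permutation(labels)

    # -- geometry -----------------------------------------------------------

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    def voxel_coordinates_mm(self) -> np.ndarray:
        """(n_voxels, 3) voxel-centre coordinates, row-major over the grid."""
        idx = np.indices(self.grid_shape).reshape(3, -1).T
        return idx * self.voxel_size_mm

    @property
    def tuned_mask(self) -> np.ndarray:
        return self.tuning_assignment >= 0

    # -- stimulus-driven activity -------------------------------------------

    def stimulus_pattern(self, orientation: float) -> ActivityPattern:
        """Noise-free pattern evoked by a grating at ``orientation`` degrees.

        Tuned voxels respond through the exponential tuning curve; untuned
        voxels carry no stimulus-driven signal.
        """
        values = np.zeros(self.n_voxels)
        m = self.tuned_mask
        values[m] = tuning_response(self._preferred[m], orientation)
        return ActivityPattern(values)

    # -- spontaneous activity -----------------------------------------------

    def _smoothing_sigma_voxels(self) -> float:
        return self.grf_kernel_mm * FWHM_TO_SIGMA / self.voxel_size_mm

    def _smoothing_std_map(self) -> np.ndarray:
        """Per-voxel SD of unit white noise after Gaussian smoothing.

        For a linear smoother the output variance per voxel is the sum of the
        squared kernel weights reaching it, computed exactly by filtering a
        field of ones with the squared (separable) kernel.
        """
        sig = self._smoothing_sigma_voxels()
        probe = np.zeros(8 * int(np.ceil(sig)) + 9)
        probe[probe.size // 2] = 1.0
        w = gaussian_filter1d(probe, sig, mode="constant")
        w2 = w**2
        var = np.ones(self.grid_shape)
        for ax in range(3):
            var = correlate1d(var, w2, axis=ax, mode="constant", origin=0)
        return np.sqrt(var).reshape(-1)

    def sample_spontaneous(self, rng_seed) -> ActivityPattern:
        """One draw of spontaneous activity under the model's noise_kind."""
        return ActivityPattern(self.sample_spontaneous_batch(1, rng_seed)[0])

    def sample_spontaneous_batch(self, n_samples: int, rng_seed) -> np.ndarray:
        """(n_samples, n_voxels) spontaneous-activity draws.

        ``rng_seed`` may be an int, SeedSequence or Generator; patterns are
        reproducible given the same seed.
        """
        rng = np.random.default_rng(rng_seed)
        if self.noise_sigma == 0:
            return np.zeros((n_samples, self.n_voxels))
        if self.noise_kind == "iid":
            return rng.standard_normal((n_samples, self.n_voxels)) * self.noise_sigma
        if self.noise_kind == "grf":
            x = rng.standard_normal((n_samples, *self.grid_shape))
            sig = self._smoothing_sigma_voxels()
            for ax in (1, 2, 3):
                x = gaussian_filter1d(x, sig, axis=ax, mode="constant")
            x = x.reshape(n_samples, -1)
            # re-standardize so every voxel has marginal SD noise_sigma
            return x / self._grf_std_map * self.noise_sigma
        # orientation mixture: independent Gaussian plus a grating signal at a
        # uniformly random orientation, with equal variance shares on tuned
        # voxels (Var(g) = Var(s) = noise_sigma**2 / 2)
        g = rng.standard_normal((n_samples, self.n_voxels)) * (
            self.noise_sigma / np.sqrt(2.0)
        )
        thetas = rng.uniform(0.0, 180.0, size=n_samples)
        s = np.zeros((n_samples, self.n_voxels))
        m = self.tuned_mask
        s[:, m] = tuning_response(self._preferred[None, m], thetas[:, None])
        return g + self.mixture_signal_scale() * s

    def mixture_signal_scale(self) -> float:
        """Scalar c applied to the random-orientation signal in the mixture.

        Chosen so that on tuned voxels the signal's variance over random
        orientations equals half of noise_sigma**2.
        """
        _, var_w = _mixture_signal_moments()
        return self.noise_sigma / np.sqrt(2.0 * var_w)

    # -- training data -------------------------------------------------------

    def generate_training_examples(
        self,
        orientations,
        n_per_class: int,
        snr: float,
        rng_seed,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Labelled noisy patterns for classifier training.

        The voxelwise SNR is the tuning-curve peak (1) over the spontaneous
        SD, so sigma = 1/snr regardless of the model's own noise_sigma.
        Returns (patterns, labels) with patterns of shape
        (n_per_class * len(orientations), n_voxels) and integer labels.
        """
        if snr <= 0:
            raise ValueError("snr must be positive")
        orientations = np.asarray(orientations, dtype=float)
        tuned_set = np.asarray(self.tuned_orientations)
        for ori in orientations:
            if circular_orientation_distance(ori, tuned_set).min() > 1e-9:
                logging.getLogger(__name__).info(
                    "training orientation %.1f deg is not a tuned orientation; "
                    "tuning curve applied as usual",
                    ori,
                )
        sigma = 1.0 / snr
        noise_model = self if self.noise_sigma == sigma else _with_sigma(self, sigma)
        n_total = n_per_class * len(orientations)
        noise = noise_model.sample_spontaneous_batch(n_total, rng_seed)
        patterns = np.empty((n_total, self.n_voxels))
        labels = np.empty(n_total, dtype=int)
        row = 0
        for ci, ori in enumerate(orientations):
            base = self.stimulus_pattern(ori).values
            patterns[row : row + n_per_class] = base + noise[row : row + n_per_class]
            labels[row : row + n_per_class] = ci
            row += n_per_class
        return patterns, labels

    # -- serialization -------------------------------------------------------

    def to_config(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "voxel_size_mm": self.voxel_size_mm,
            "tuned_orientations": list(self.tuned_orientations),
            "fraction_tuned": self.fraction_tuned,
            "noise_sigma": self.noise_sigma,
            "noise_kind": self.noise_kind,
            "grf_kernel_mm": self.grf_kernel_mm,
            "assignment_seed": self.assignment_seed,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "VoxelModel":
        cfg = dict(cfg)
        cfg["grid_shape"] = tuple(cfg["grid_shape"])
        cfg["tuned_orientations"] = tuple(cfg["tuned_orientations"])
        return cls(**cfg)

    def pattern_to_frame(self, pattern: ActivityPattern):
        """Pattern as a DataFrame (voxel_index, x, y, z, value) for CSV export."""
        import pandas as pd

        xyz = self.voxel_coordinates_mm()
        return pd.DataFrame(
            {
                "voxel_index": np.arange(self.n_voxels),
                "x": xyz[:, 0],
                "y": xyz[:, 1],
                "z": xyz[:, 2],
                "value": pattern.values,
            }
        )


def _with_sigma(model: VoxelModel, sigma: float) -> VoxelModel:
    cfg = model.to_config()
    cfg["noise_sigma"] = sigma
    out = VoxelModel.from_config(cfg)
    out.tuning_assignment = model.tuning_assignment
    out.__post_init__()
    return out
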