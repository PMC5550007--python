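"""Outcome analysis of conditioning runs.

Learning-curve categorization (successful / trending / none / anti),
2-D surface projection of voxel maps, and per-pattern correlation of final
conditioned patterns against the true orientation patterns and the
classifier weight maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .automatic_learner import (
    INTERMITTENT_ALPHA_PER_TRIAL,
    LearningCurve,
    run_conditioning_experiment,
)
from .decoder import (
    AUTOMATIC_ORIENTATIONS,
    AUTOMATIC_SPARSITY,
    PatternClassifier,
    train_classifier,
)
from .v1_model import VoxelModel

__all__ = [
    "categorize_learning",
    "pattern_correlations",
    "CorrelationReport",
    "SurfaceProjection",
    "build_surface_model",
    "run_surface_pattern_experiment",
]

logger = logging.getLogger(__name__)


def categorize_learning(
    curve: LearningCurve, chance: float, slope_alpha: float = 0.05
) -> tuple[str, float]:
    """Classify a learning curve against the chance level.

    ``successful`` if the final 50% CI lies entirely above chance, ``anti``
    if entirely below, ``none`` if the OLS slope of the mean curve is not
    distinguishable from zero (two-sided test at ``slope_alpha``), otherwise
    ``trending``.  Also returns the final mean value used for ranking.
    """
    final_lo, final_hi = float(curve.ci25[-1]), float(curve.ci75[-1])
    if final_lo > chance:
        return "successful", curve.final_mean
    if final_hi < chance:
        return "anti", curve.final_mean
    res = stats.linregress(curve.time_s, curve.mean)
    if res.pvalue >= slope_alpha:
        return "none", curve.final_mean
    return "trending", curve.final_mean


@dataclass
class CorrelationReport:
    """Mean per-pattern Pearson correlations with reference maps.

    ``mean_r`` maps (reference_name, orientation) -> mean r across patterns;
    the mean is taken over per-pattern correlations, never computed from the
    mean pattern.  ``n_excluded`` counts zero-variance patterns dropped.
    """

    orientations: tuple[float, ...]
    mean_r: dict = field(default_factory=dict)
    per_pattern: dict = field(default_factory=dict)
    n_excluded: int = 0

    def to_frame(self):
        import pandas as pd

        rows = [
            {"reference": ref, "orientation": ori, "mean_r": r}
            for (ref, ori), r in self.mean_r.items()
        ]
        return pd.DataFrame(rows)


def _rowwise_pearson(patterns: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``patterns`` with ``reference``; nan if degenerate."""
    x = patterns - patterns.mean(axis=1, keepdims=True)
    y = reference - reference.mean()
    xs = np.sqrt((x**2).sum(axis=1))
    ys = np.sqrt((y**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x @ y) / (xs * ys)
    return r


def pattern_correlations(
    conditioned: np.ndarray,
    truth: dict[float, np.ndarray],
    weights: dict[float, np.ndarray],
) -> CorrelationReport:
    """Correlate each conditioned pattern with every reference map.

    ``truth`` and ``weights`` map orientation (deg) to a voxel vector on the
    same voxel set as the (n_patterns, n_voxels) conditioned array.
    """
    conditioned = np.atleast_2d(np.asarray(conditioned, dtype=float))
    report = CorrelationReport(orientations=tuple(truth))
    degenerate = conditioned.std(axis=1) == 0
    report.n_excluded = int(degenerate.sum())
    if report.n_excluded:
        logger.warning(
            "%d zero-variance conditioned patterns excluded from correlation means",
            report.n_excluded,
        )
    for name, maps in (("true_pattern", truth), ("weight_map", weights)):
        for ori, ref in maps.items():
            r = _rowwise_pearson(conditioned, np.asarray(ref, dtype=float))
            r[degenerate] = np.nan
            report.per_pattern[(name, ori)] = r
            report.mean_r[(name, ori)] = float(np.nanmean(r))
    return report


@dataclass
class SurfaceProjection:
    """Random placement of voxels onto a square surface for display.

    The placement is a bijection shared by every map of one simulated
    participant, so all correlations computed on the projected maps equal
    those on the raw voxel vectors.
    """

    side: int
    placement: np.ndarray  # permutation: surface cell i shows voxel placement[i]

    @classmethod
    def random(cls, n_voxels: int, rng_seed=0) -> "SurfaceProjection":
        side = int(np.sqrt(n_voxels))
        if side * side != n_voxels:
            raise ValueError("voxel count must be a perfect square for projection")
        rng = np.random.default_rng(rng_seed)
        return cls(side=side, placement=rng.permutation(n_voxels))

    def project(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return values[self.placement].reshape(self.side, self.side)


def build_surface_model(
    noise_kind: str = "iid", noise_sigma: float = 0.5, assignment_seed: int = 0
) -> VoxelModel:
    """The 400-voxel surface model: 200 tuned + 200 untuned voxels on 20x20.

    Same tuning curve, orientations and per-voxel noise scale as the
    1000-voxel cube; only the voxel count and geometry differ.
    """
    return VoxelModel(
        grid_shape=(20, 20, 1),
        tuned_orientations=tuple(np.arange(8) * 22.5),
        fraction_tuned=0.5,
        noise_sigma=noise_sigma,
        noise_kind=noise_kind,
        assignment_seed=assignment_seed,
    )


def run_surface_pattern_experiment(
    noise_kind: str = "iid",
    reps: int = 1000,
    rng_seed=0,
    hours: float = 5.0,
    classifier: PatternClassifier | None = None,
    model: VoxelModel | None = None,
    target_orientation: float = 10.0,
    return_patterns: bool = False,
):
    """Surface-model conditioning and its pattern-correlation analysis.

    Conditions ``reps`` simulated participants with the HRF physiological
    response and the intermittent cue schedule on the 400-voxel surface
    model, then correlates each final conditioned pattern with the three
    true orientation patterns and the three classifier weight maps.

    ``noise_kind`` selects the spontaneous-activity model during
    conditioning: "iid" (uncorrelated Gaussian) or "orientation_mixture"
    (half Gaussian noise, half a randomly oriented grating signal).  The
    decoder itself is trained once on uncorrelated-noise examples.
    """
    ss = np.random.SeedSequence(rng_seed) if not isinstance(
        rng_seed, np.random.SeedSequence
    ) else rng_seed
    train_seed, run_seed = ss.spawn(2)
    if model is None:
        model = build_surface_model(noise_kind=noise_kind)
    if classifier is None:
        base = build_surface_model(noise_kind="iid")
        patterns, labels = base.generate_training_examples(
            AUTOMATIC_ORIENTATIONS, n_per_class=70, snr=2.0, rng_seed=train_seed
        )
        classifier = train_classifier(
            patterns,
            labels,
            AUTOMATIC_ORIENTATIONS,
            sparsity_control=AUTOMATIC_SPARSITY,
            rng_seed=1,
        )
    target_class = classifier.class_index(target_orientation)
    curve, conditioned = run_conditioning_experiment(
        model,
        classifier,
        physio="hrf",
        internal="cue",
        schedule="intermittent",
        hours=hours,
        reps=reps,
        alpha_per_20s=INTERMITTENT_ALPHA_PER_TRIAL,
        target_class=target_class,
        rng_seed=run_seed,
        return_patterns=True,
    )
    truth = {
        ori: model.stimulus_pattern(ori).values for ori in classifier.class_orientations
    }
    weights = {ori: classifier.weight_map(ori) for ori in classifier.class_orientations}
    report = pattern_correlations(conditioned, truth, weights)
    if return_patterns:
        return report, curve, conditioned
    return report, curve
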