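"""Configuration, output bundles, fixtures and named experiments.

Each named experiment reproduces one of the package's headline simulations
(two-voxel demo, internal-model grid, surface-pattern correlations, cognitive
target searches) and writes CSV/JSON outputs plus a manifest recording the
resolved configuration and master seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .analysis import categorize_learning, run_surface_pattern_experiment
from .automatic_learner import (
    LearningCurve,
    condition_grid,
    run_conditioning_experiment,
    run_continuous_batch,
    two_voxel_classifier,
)
from .cognitive_env import (
    BinarySearchAgent,
    GreedyHillClimberAgent,
    HoldStillAgent,
    JumpToTargetAgent,
    run_continuous_search,
    run_intermittent_search,
)
from .decoder import (
    AUTOMATIC_ORIENTATIONS,
    AUTOMATIC_SPARSITY,
    COGNITIVE_ORIENTATIONS,
    train_classifier,
)
from .hemodynamics import FILTER_KINDS, make_filter
from .v1_model import VoxelModel

__all__ = ["ExperimentConfig", "run_named_experiment", "generate_fixtures", "make_agent"]

EXPERIMENTS = (
    "two-voxel-demo",
    "internal-model-grid",
    "surface-patterns",
    "cognitive-continuous",
    "cognitive-intermittent",
    "custom",
)


@dataclass
class ExperimentConfig:
    """Resolved configuration of a named experiment run."""

    experiment: str
    seed: int = 0
    reps: int = 100
    hours: float = 5.0
    out_dir: str = "scratch/out"
    physio: str = "hrf"
    internal: str = "cue"
    schedule: str = "intermittent"
    agent: str = "greedy"
    filter_kind: str = "impulse"
    target: float = 45.0
    snr: float = 2.0
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        return cls(**json.loads(text))


def make_agent(name: str, target: float):
    agents = {
        "jump": lambda: JumpToTargetAgent(target),
        "hold": HoldStillAgent,
        "greedy": GreedyHillClimberAgent,
        "binary": BinarySearchAgent,
    }
    if name not in agents:
        raise ValueError(f"unknown agent {name!r}; choose from {sorted(agents)}")
    return agents[name]()


def _default_model(snr: float = 2.0) -> VoxelModel:
    return VoxelModel(noise_sigma=1.0 / snr)


def _train_automatic_classifier(model: VoxelModel, seed) -> "object":
    patterns, labels = model.generate_training_examples(
        AUTOMATIC_ORIENTATIONS, n_per_class=70, snr=2.0, rng_seed=seed
    )
    return train_classifier(
        patterns,
        labels,
        AUTOMATIC_ORIENTATIONS,
        sparsity_control=AUTOMATIC_SPARSITY,
        rng_seed=1,
    )


def _train_cognitive_classifier(model: VoxelModel, seed) -> "object":
    patterns, labels = model.generate_training_examples(
        COGNITIVE_ORIENTATIONS, n_per_class=100, snr=2.0, rng_seed=seed
    )
    return train_classifier(patterns, labels, COGNITIVE_ORIENTATIONS, rng_seed=1)


def run_named_experiment(config: ExperimentConfig) -> dict:
    """Run one named experiment and write its output bundle.

    Returns a manifest dict (also written as manifest.json in the output
    directory) listing the files produced.
    """
    if config.experiment not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {config.experiment!r}; choose from {EXPERIMENTS}"
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    ss = np.random.SeedSequence(config.seed)
    files: list[str] = []

    def write_curve(curve, name):
        path = out / f"{name}.csv"
        curve.to_frame().to_csv(path, index=False)
        files.append(path.name)

    if config.experiment == "two-voxel-demo":
        files += _run_two_voxel_demo(config, out, ss)
    elif config.experiment in ("internal-model-grid", "custom"):
        model = _default_model(config.snr)
        clf_seed, run_seed = ss.spawn(2)
        classifier = _train_automatic_classifier(model, clf_seed)
        conditions = (
            condition_grid()
            if config.experiment == "internal-model-grid"
            else [
                {
                    "schedule": config.schedule,
                    "physio": config.physio,
                    "internal": config.internal,
                }
            ]
        )
        summary = []
        cond_seeds = run_seed.spawn(len(conditions))
        for cond, cond_seed in zip(conditions, cond_seeds):
            curve = run_conditioning_experiment(
                model,
                classifier,
                physio=cond["physio"],
                internal=cond["internal"],
                schedule=cond["schedule"],
                hours=config.hours,
                reps=config.reps,
                rng_seed=cond_seed,
            )
            name = f"curve_{cond['physio']}_{cond['internal']}_{cond['schedule']}"
            write_curve(curve.smoothed(), name)
            category, final = categorize_learning(
                curve.smoothed(), chance=1.0 / classifier.n_classes
            )
            summary.append({**cond, "category": category, "final_mean": final})
        with open(out / "summary.json", "w") as f:
            json.dump(summary, f, indent=2)
        files.append("summary.json")
    elif config.experiment == "surface-patterns":
        for noise_kind in ("iid", "orientation_mixture"):
            report, curve = run_surface_pattern_experiment(
                noise_kind=noise_kind, reps=config.reps, rng_seed=ss, hours=config.hours
            )
            report.to_frame().to_csv(out / f"correlations_{noise_kind}.csv", index=False)
            write_curve(curve, f"curve_{noise_kind}")
            files.append(f"correlations_{noise_kind}.csv")
    elif config.experiment.startswith("cognitive"):
        files += _run_cognitive(config, out, ss)

    manifest = {
        "config": json.loads(config.to_json()),
        "seed": config.seed,
        "version": __version__,
        "wall_time_s": round(time.time() - t0, 3),
        "files": files,
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest


def _run_two_voxel_demo(config: ExperimentConfig, out: Path, ss) -> list[str]:
    """Two-voxel impulse learning vs HRF-filtered learning without an internal model."""
    classifier = two_voxel_classifier()
    model = VoxelModel(
        grid_shape=(2, 1, 1), fraction_tuned=0.0, noise_sigma=0.25, noise_kind="iid"
    )
    files = []
    for name, physio in (("impulse", "impulse"), ("hrf_no_model", "hrf")):
        f = run_continuous_batch(
            model,
            classifier,
            target_class=0,
            physio=make_filter(physio),
            internal=make_filter("impulse"),
            n_trs=config.extra.get("n_trs", 200),
            alpha=1.0,
            n_reps=config.reps,
            rng_seed=ss.spawn(1)[0],
        )
        curve = LearningCurve.from_trajectories(f, 2.0, {"demo": name})
        path = out / f"two_voxel_{name}.csv"
        curve.to_frame().to_csv(path, index=False)
        files.append(path.name)
    return files


def _run_cognitive(config: ExperimentConfig, out: Path, ss) -> list[str]:
    model = VoxelModel(noise_sigma=0.1)  # runtime SNR of 10 for a reliable signal
    clf_seed, run_seed = ss.spawn(2)
    classifier = _train_cognitive_classifier(model, clf_seed)
    agent = make_agent(config.agent, config.target)
    if config.experiment == "cognitive-continuous":
        record = run_continuous_search(
            agent,
            config.target,
            make_filter(config.filter_kind),
            model,
            classifier,
            rng_seed=run_seed,
        )
        record.tr_frame().to_csv(out / "session_trs.csv", index=False)
        files = ["session_trs.csv"]
    else:
        record = run_intermittent_search(
            agent,
            config.target,
            make_filter(config.filter_kind),
            model,
            classifier,
            rng_seed=run_seed,
        )
        record.trial_frame().to_csv(out / "session_trials.csv", index=False)
        files = ["session_trials.csv"]
    with open(out / "session_summary.json", "w") as f:
        json.dump(
            {
                "success": record.success,
                "trs_elapsed": record.trs_elapsed,
                "n_trials": record.n_trials,
                "time_to_target_s": record.time_to_target_s,
            },
            f,
            indent=2,
        )
    files.append("session_summary.json")
    return files


def export_array_archive(path: str | Path, **arrays) -> Path:
    """Dump named arrays to a compressed .npz archive (portable binary form)."""
    path = Path(path).with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **{k: np.asarray(v) for k, v in arrays.items()})
    return path


def generate_fixtures(seed: int = 0, out_dir: str | Path = "scratch/fixtures") -> dict:
    """Write the small deterministic bundle used by the unit-test suite.

    Contents: the two-voxel demo model, a 50-voxel mini brain, a pre-trained
    mini 3-way classifier, one 20-TR spontaneous trajectory, and every
    filter's weight table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    train_seed, traj_seed = ss.spawn(2)
    mini = VoxelModel(
        grid_shape=(50, 1, 1), fraction_tuned=0.4, noise_sigma=0.5, noise_kind="iid",
        assignment_seed=seed,
    )
    with open(out / "mini_model.json", "w") as f:
        json.dump(mini.to_config(), f, indent=2)
    patterns, labels = mini.generate_training_examples(
        AUTOMATIC_ORIENTATIONS, n_per_class=30, snr=2.0, rng_seed=train_seed
    )
    clf = train_classifier(patterns, labels, AUTOMATIC_ORIENTATIONS, rng_seed=1)
    clf.to_frame().to_csv(out / "mini_classifier.csv", index=False)
    traj = mini.sample_spontaneous_batch(20, traj_seed)
    np.savetxt(out / "trajectory_20tr.csv", traj, delimiter=",")
    for kind in FILTER_KINDS:
        make_filter(kind).to_frame().to_csv(out / f"filter_{kind}.csv", index=False)
    manifest = {
        "seed": seed,
        "files": sorted(p.name for p in out.iterdir()),
        "version": __version__,
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return {"model": mini, "classifier": clf, "trajectory": traj, "manifest": manifest}
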