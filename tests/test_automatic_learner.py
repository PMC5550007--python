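import numpy as np
import pytest

from neurofb.automatic_learner import (
    LearnerState,
    LearningCurve,
    TrialWindows,
    condition_grid,
    credited_activity_expanded,
    run_conditioning_experiment,
    run_continuous_batch,
    run_intermittent_batch,
    run_intermittent_trial,
    step_continuous,
    step_impulse,
    two_voxel_classifier,
)
from neurofb.decoder import softmax
from neurofb.hemodynamics import make_filter
from neurofb.v1_model import VoxelModel


@pytest.fixture
def two_voxel_model():
    return VoxelModel(
        grid_shape=(2, 1, 1), fraction_tuned=0.0, noise_sigma=0.25, noise_kind="iid"
    )


def fresh_state(clf, alpha=1.0, physio="impulse", internal="impulse"):
    return LearnerState(
        classifier=clf,
        target_class=0,
        alpha=alpha,
        physio=make_filter(physio),
        internal=make_filter(internal),
    )


class TestImpulseStep:
    def test_single_step_closed_form(self, two_voxel_model):
        clf = two_voxel_classifier()
        state = fresh_state(clf)
        a_s = np.array([1.0, -1.0])
        step_impulse(state, two_voxel_model, a_s=a_s)
        f = softmax(np.array([2.0, -2.0]))[0]
        l = f - 0.5
        assert state.f_history[-1] == pytest.approx(f)
        assert l == pytest.approx(0.482, abs=1e-3)
        np.testing.assert_allclose(state.a_c, [l, -l])

    def test_alpha_zero_leaves_conditioned_activity_untouched(self, two_voxel_model):
        clf = two_voxel_classifier()
        state = fresh_state(clf, alpha=0.0)
        for seed in range(20):
            step_impulse(state, two_voxel_model, rng_seed=seed)
        assert not state.a_c.any()

    def test_reduces_to_continuous_with_impulse_filters(self, two_voxel_model):
        clf = two_voxel_classifier()
        rng = np.random.default_rng(3)
        noise = rng.standard_normal((25, 2)) * 0.25
        s1 = fresh_state(clf)
        s2 = fresh_state(clf)
        for n in range(25):
            step_impulse(s1, two_voxel_model, a_s=noise[n])
            step_continuous(s2, two_voxel_model, a_s=noise[n])
        np.testing.assert_allclose(s1.a_c, s2.a_c)
        np.testing.assert_allclose(s1.f_history, s2.f_history)

    def test_noise_free_target_drive_learns_monotonically(self, two_voxel_model):
        # feeding the desired pattern every TR: f climbs to its softmax ceiling
        clf = two_voxel_classifier()
        state = fresh_state(clf, alpha=0.5)
        target = np.array([1.0, -1.0])
        for _ in range(30):
            step_impulse(state, two_voxel_model, a_s=target)
        f = np.array(state.f_history)
        assert np.all(np.diff(f) > -1e-12)
        assert f[-1] > 0.99


class TestContinuousStep:
    def test_buffer_convolution_matches_expanded_sum(self, two_voxel_model, rng):
        clf = two_voxel_classifier()
        state = fresh_state(clf, physio="hrf", internal="blur")
        for n in range(30):
            a_s = rng.standard_normal(2) * 0.25
            expanded_before = credited_activity_expanded(
                np.vstack([(a_s + state.a_c), state.memory[:-1]]), state.internal
            )
            prev_ac = state.a_c.copy()
            step_continuous(state, two_voxel_model, a_s=a_s)
            l = state.f_history[-1] - (
                state.f_history[-2] if len(state.f_history) > 1 else 0.5
            )
            np.testing.assert_allclose(
                state.a_c, prev_ac + state.alpha * l * expanded_before, atol=1e-12
            )

    def test_memory_buffer_length(self, two_voxel_model):
        clf = two_voxel_classifier()
        state = fresh_state(clf, physio="hrf", internal="delay")
        L = max(state.physio.L, state.internal.L)
        assert state.memory.shape[0] == L + 1
        for seed in range(3):
            step_continuous(state, two_voxel_model, rng_seed=seed)
        assert state.memory.shape[0] == L + 1


class TestIntermittentTrial:
    def test_zero_learning_signal_leaves_ac_unchanged(self, two_voxel_model):
        clf = two_voxel_classifier()
        state = fresh_state(clf, physio="hrf")
        # noise-free: trial feedback equals f_prev baseline after one trial
        quiet = VoxelModel(
            grid_shape=(2, 1, 1), fraction_tuned=0.0, noise_sigma=0.0, noise_kind="iid"
        )
        run_intermittent_trial(state, quiet, rng_seed=0)
        ac_after_first = state.a_c.copy()
        run_intermittent_trial(state, quiet, rng_seed=1)
        np.testing.assert_allclose(state.a_c, ac_after_first, atol=1e-12)

    def test_conditioned_activity_gated_to_cue_period(self, two_voxel_model):
        clf = two_voxel_classifier()
        state = fresh_state(clf, physio="delay")
        state.a_c = np.array([5.0, -5.0])
        noise = np.zeros((6, 2))
        before = state.a_c.copy()
        run_intermittent_trial(state, two_voxel_model, a_s=noise)
        # delay-3 physio: wait TRs replay cue TRs, where a_c was gated on
        f_trial = state.f_history[-1]
        assert f_trial == pytest.approx(softmax(np.array([20.0, -20.0]))[0])
        # outside the cue the activity was a_s only (zero) by construction
        assert np.all(np.sign(state.a_c) == np.sign(before))

    def test_windows_must_be_ordered(self):
        with pytest.raises(ValueError):
            TrialWindows(cue=(0, 3), wait=(2, 5))


class TestBatchRunners:
    def test_continuous_batch_matches_stepper(self, two_voxel_model):
        clf = two_voxel_classifier()
        rng = np.random.default_rng(5)
        noise = rng.standard_normal((40, 2)) * 0.25

        class Replay:
            n_voxels = 2

            def __init__(self):
                self.i = 0

            def sample_spontaneous_batch(self, n, rng):
                out = noise[self.i][None, :].copy()
                self.i += 1
                return out

        f_batch = run_continuous_batch(
            Replay(), clf, 0, make_filter("hrf"), make_filter("delay"),
            n_trs=40, alpha=1.0, n_reps=1,
        )
        state = fresh_state(clf, physio="hrf", internal="delay")
        for n in range(40):
            step_continuous(state, two_voxel_model, a_s=noise[n])
        np.testing.assert_allclose(f_batch[0], state.f_history, atol=1e-12)

    def test_intermittent_batch_matches_stepper(self, two_voxel_model):
        clf = two_voxel_classifier()
        rng = np.random.default_rng(6)
        noise = rng.standard_normal((5, 6, 2)) * 0.25

        class Replay:
            n_voxels = 2

            def __init__(self):
                self.i = 0

            def sample_spontaneous_batch(self, n, rng):
                out = noise[self.i].reshape(n, 2).copy()
                self.i += 1
                return out

        f_batch = run_intermittent_batch(
            Replay(), clf, 0, make_filter("hrf"), n_trials=5, alpha=1.0, n_reps=1
        )
        state = fresh_state(clf, physio="hrf")
        for k in range(5):
            run_intermittent_trial(state, two_voxel_model, a_s=noise[k])
        np.testing.assert_allclose(f_batch[0], state.f_history, atol=1e-12)

    def test_seeded_reproducibility(self, two_voxel_model):
        clf = two_voxel_classifier()
        a = run_continuous_batch(
            two_voxel_model, clf, 0, make_filter("blur"), make_filter("blur"),
            n_trs=30, alpha=1.0, n_reps=4, rng_seed=11,
        )
        b = run_continuous_batch(
            two_voxel_model, clf, 0, make_filter("blur"), make_filter("blur"),
            n_trs=30, alpha=1.0, n_reps=4, rng_seed=11,
        )
        np.testing.assert_array_equal(a, b)

    def test_alpha_zero_is_stationary_at_baseline(self, two_voxel_model):
        clf = two_voxel_classifier()
        f = run_continuous_batch(
            two_voxel_model, clf, 0, make_filter("impulse"), make_filter("impulse"),
            n_trs=300, alpha=0.0, n_reps=300, rng_seed=1,
        )
        # two-class softmax is odd around chance: E[f] stays at 1/2
        assert f[:, :50].mean() == pytest.approx(0.5, abs=0.01)
        assert f[:, -50:].mean() == pytest.approx(0.5, abs=0.01)


class TestExperiments:
    def test_condition_grid_enumerates_twenty(self):
        grid = condition_grid()
        assert len(grid) == 20
        assert sum(c["schedule"] == "intermittent" for c in grid) == 4
        assert len({(c["physio"], c["internal"], c["schedule"]) for c in grid}) == 20

    def test_five_hours_gives_900_trials_and_9000_trs(self, two_voxel_model):
        clf = two_voxel_classifier()
        curve = run_conditioning_experiment(
            two_voxel_model, clf, physio="hrf", internal="cue",
            schedule="intermittent", hours=0.5, reps=3, rng_seed=0,
        )
        assert len(curve.mean) == 90  # 0.5 h * 3600 / 20 s per trial
        curve_c = run_conditioning_experiment(
            two_voxel_model, clf, physio="impulse", internal="impulse",
            schedule="continuous", hours=0.1, reps=3, rng_seed=0,
        )
        assert len(curve_c.mean) == 180  # 0.1 h * 1800 TRs
        assert curve_c.condition["alpha_per_20s"] == 0.01

    def test_cue_internal_invalid_for_continuous(self, two_voxel_model):
        clf = two_voxel_classifier()
        with pytest.raises(ValueError):
            run_conditioning_experiment(
                two_voxel_model, clf, physio="hrf", internal="cue",
                schedule="continuous", hours=0.1, reps=1,
            )

    def test_curve_aggregation_and_ci_order(self, rng):
        f = rng.random((50, 40))
        curve = LearningCurve.from_trajectories(f, 2.0)
        assert np.all(curve.ci25 <= curve.mean + 1e-12)
        assert np.all(curve.mean <= curve.ci75 + 1e-12)
        sm = curve.smoothed(20.0)
        assert len(sm.mean) == len(curve.mean)
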