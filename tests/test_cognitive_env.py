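import numpy as np
import pytest

from neurofb.cognitive_env import (
    TIMINGS,
    BinarySearchAgent,
    HoldStillAgent,
    JumpToTargetAgent,
    build_block_schedule,
    circular_mean_orientation,
    run_continuous_search,
    run_intermittent_search,
    time_to_target_intermittent,
)
from neurofb.decoder import AUTOMATIC_ORIENTATIONS
from neurofb.hemodynamics import make_filter
from neurofb.v1_model import VoxelModel


@pytest.fixture(scope="module")
def quiet_model(mini_model):
    m = VoxelModel(**{**mini_model.to_config(), "noise_sigma": 0.0})
    m.tuning_assignment = mini_model.tuning_assignment
    m.__post_init__()
    return m


class TestTrialTimings:
    @pytest.mark.parametrize(
        "name,parts,total",
        [
            ("realtime", (3, 6, 6, 2, 3), 20),
            ("x2", (3, 3, 3, 2, 2), 13),
            ("x6", (3, 1, 1, 2, 1), 8),
        ],
    )
    def test_component_durations_and_totals(self, name, parts, total):
        t = TIMINGS[name]
        assert (t.select_s, t.stimulus_s, t.delay_s, t.feedback_s, t.wait_s) == parts
        assert t.total_s == total

    def test_acceleration_does_not_change_scores(self, mini_model, mini_classifier):
        records = {
            name: run_intermittent_search(
                JumpToTargetAgent(70.0),
                70.0,
                make_filter("hrf"),
                mini_model,
                mini_classifier,
                timing=TIMINGS[name],
                max_trials=5,
                rng_seed=77,
            )
            for name in TIMINGS
        }
        scores = {
            name: [row["score"] for row in rec.trial_log] for name, rec in records.items()
        }
        assert scores["realtime"] == scores["x2"] == scores["x6"]


class TestTimeToTarget:
    @pytest.mark.parametrize("n,expected", [(1, 15.0), (3, 55.0), (10, 195.0)])
    def test_formula(self, n, expected):
        assert time_to_target_intermittent(n) == expected

    def test_rejects_zero_trials(self):
        with pytest.raises(ValueError):
            time_to_target_intermittent(0)


class TestCircularMean:
    def test_wraparound_average(self):
        assert circular_mean_orientation([175.0, 5.0]) == pytest.approx(0.0, abs=1e-9)

    def test_plain_average_away_from_wrap(self):
        assert circular_mean_orientation([40.0, 50.0]) == pytest.approx(45.0)


class TestContinuousSearch:
    def test_agent_at_target_succeeds_at_first_check(
        self, quiet_model, mini_classifier
    ):
        # target at the 0 deg start: no rotation needed, threshold met immediately
        rec = run_continuous_search(
            HoldStillAgent(),
            10.0,
            make_filter("impulse"),
            quiet_model,
            mini_classifier,
            max_trs=20,
            rng_seed=0,
        )
        assert rec.success and rec.trs_elapsed == 3
        assert rec.time_to_target_s == 6.0

    def test_holding_far_from_target_never_succeeds(self, quiet_model, mini_classifier):
        rec = run_continuous_search(
            HoldStillAgent(),
            70.0,  # far from the 0 deg start; agent never moves
            make_filter("impulse"),
            quiet_model,
            mini_classifier,
            max_trs=30,
            rng_seed=0,
        )
        assert not rec.success
        assert max(r["feedback"] for r in rec.tr_log) < 0.5

    def test_jump_agent_reaches_any_target(self, quiet_model, mini_classifier):
        for target in AUTOMATIC_ORIENTATIONS:
            rec = run_continuous_search(
                JumpToTargetAgent(target),
                target,
                make_filter("impulse"),
                quiet_model,
                mini_classifier,
                max_trs=40,
                rng_seed=0,
            )
            assert rec.success

    def test_deterministic_given_seed(self, mini_model, mini_classifier):
        runs = [
            run_continuous_search(
                JumpToTargetAgent(70.0),
                70.0,
                make_filter("hrf"),
                mini_model,
                mini_classifier,
                max_trs=25,
                rng_seed=123,
            )
            for _ in range(2)
        ]
        assert runs[0].trs_elapsed == runs[1].trs_elapsed
        np.testing.assert_array_equal(
            [r["feedback"] for r in runs[0].tr_log],
            [r["feedback"] for r in runs[1].tr_log],
        )

    def test_tr_indices_strictly_increasing(self, mini_model, mini_classifier):
        rec = run_continuous_search(
            HoldStillAgent(),
            10.0,
            make_filter("blur"),
            mini_model,
            mini_classifier,
            max_trs=15,
            rng_seed=5,
        )
        trs = [r["tr"] for r in rec.tr_log]
        assert trs == sorted(set(trs))


class TestIntermittentSearch:
    def test_impulse_filter_rejected(self, mini_model, mini_classifier):
        with pytest.raises(ValueError):
            run_intermittent_search(
                HoldStillAgent(),
                10.0,
                make_filter("impulse"),
                mini_model,
                mini_classifier,
            )

    def test_oracle_agent_succeeds_first_trial_noise_free(
        self, quiet_model, mini_classifier
    ):
        rec = run_intermittent_search(
            JumpToTargetAgent(70.0),
            70.0,
            make_filter("delay"),
            quiet_model,
            mini_classifier,
            rng_seed=0,
        )
        assert rec.success and rec.n_trials == 1
        assert rec.time_to_target_s == 15.0

    def test_binary_search_trial_bound_noise_free(self, quiet_model, mini_classifier):
        # over the 3 class orientations: bound is ceil(log2(8)) + 1 trials
        for target in AUTOMATIC_ORIENTATIONS:
            agent = BinarySearchAgent(class_orientations=AUTOMATIC_ORIENTATIONS)
            rec = run_intermittent_search(
                agent,
                target,
                make_filter("delay"),
                quiet_model,
                mini_classifier,
                max_trials=10,
                rng_seed=0,
            )
            assert rec.success and rec.n_trials <= 4

    def test_hold_still_fails_on_far_target(self, quiet_model, mini_classifier):
        rec = run_intermittent_search(
            HoldStillAgent(),
            70.0,
            make_filter("delay"),
            quiet_model,
            mini_classifier,
            max_trials=5,
            rng_seed=0,
        )
        assert not rec.success


class TestBlockSchedule:
    def test_continuous_block_structure(self):
        sched = build_block_schedule("continuous", rng_seed=4)
        assert sched[0]["filter"] == "impulse"  # familiarization block first
        blocks = {}
        for row in sched:
            blocks.setdefault(row["block"], []).append(row)
        assert len(blocks) == 4
        for rows in blocks.values():
            visible = [r for r in rows if r["visible"]]
            hidden = [r for r in rows if not r["visible"]]
            assert [r["target"] for r in visible] == [45.0, 90.0, 135.0]
            assert len(hidden) == 14
            counts = np.unique([r["target"] for r in hidden], return_counts=True)[1]
            assert np.all(counts <= 2)
        assert sorted(b[0]["filter"] for b in blocks.values()) == sorted(
            ["impulse", "hrf", "blur", "delay"]
        )

    def test_intermittent_schedule_counts(self):
        sched = build_block_schedule("intermittent", rng_seed=4)
        assert len(sched) == 63  # 7 blocks of 9 targets
        counts = np.unique([r["target"] for r in sched], return_counts=True)[1]
        assert counts.min() >= 7 and counts.max() <= 8  # as balanced as 63/8 allows

    def test_reproducible(self):
        assert build_block_schedule("continuous", 11) == build_block_schedule(
            "continuous", 11
        )

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            build_block_schedule("mixed", 0)
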