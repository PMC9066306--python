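"""Session structure, stimulus generation and exclusion rules."""

import numpy as np
import pytest

from equivnoise.errors import IncompleteInputError, ParameterDomainError
from equivnoise.tasks import (
    TASK_NAMES,
    TaskConfig,
    TaskOutcome,
    TrialSpec,
    apply_exclusions,
    build_session,
    default_configs,
    run_criterion_phase,
    sample_stimulus,
)

CONFIGS = default_configs()


class TestSessionStructure:
    @pytest.mark.parametrize(
        "task,total", [("motion_avg", 165), ("ori_avg", 165), ("motion_coh", 90), ("ori_coh", 90)]
    )
    def test_trial_totals(self, task, total):
        # averaging: two 75-trial staircases + 15 catch; coherence: one + 15
        assert len(build_session(CONFIGS[task], seed=1)) == total

    def test_condition_counts(self):
        trials = build_session(CONFIGS["motion_avg"], seed=5)
        conds = [t.condition for t in trials]
        assert conds.count("no_noise") == 75
        assert conds.count("high_noise") == 75
        assert conds.count("catch") == 15

    def test_same_seed_same_session(self):
        a = build_session(CONFIGS["motion_coh"], seed=42)
        b = build_session(CONFIGS["motion_coh"], seed=42)
        assert [(t.condition, t.side, t.stimulus_value) for t in a] == [
            (t.condition, t.side, t.stimulus_value) for t in b
        ]
        c = build_session(CONFIGS["motion_coh"], seed=43)
        assert [(t.condition, t.side) for t in a] != [(t.condition, t.side) for t in c]

    def test_sides_counterbalanced(self):
        sides = [
            t.side
            for s in range(40)
            for t in build_session(CONFIGS["ori_coh"], seed=s)
        ]
        frac = np.mean([s > 0 for s in sides])
        n = len(sides)
        assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_blocks_cover_session(self):
        trials = build_session(CONFIGS["motion_avg"], seed=2)
        blocks = [t.block for t in trials]
        assert set(blocks) == {0, 1, 2, 3}
        assert blocks == sorted(blocks)  # contiguous chunks


class TestStimuli:
    def test_no_noise_degenerate(self, rng):
        trial = TrialSpec(1, "no_noise", side=-1, stimulus_value=5.0)
        es = sample_stimulus(trial, CONFIGS["motion_avg"], rng)
        np.testing.assert_allclose(es.values, (-5.0) % 360.0)

    def test_high_noise_zero_sd_equals_fixed_offset(self, rng):
        trial = TrialSpec(1, "high_noise", side=1, stimulus_value=0.0)
        es = sample_stimulus(trial, CONFIGS["motion_avg"], rng)
        np.testing.assert_allclose(es.values, 45.0)
        assert len(es.values) == 100

    def test_coherence_signal_count(self, rng):
        trial = TrialSpec(1, "coherence", side=1, stimulus_value=0.40)
        es = sample_stimulus(trial, CONFIGS["motion_coh"], rng)
        assert es.signal_mask.sum() == 40
        np.testing.assert_allclose(es.values[es.signal_mask], 90.0)

    def test_catch_equals_criterion_stimulus(self, rng):
        # averaging catch: SD 0 at the fixed offset; coherence catch: 100% signal
        avg = sample_stimulus(TrialSpec(1, "catch", 1, 45.0), CONFIGS["motion_avg"], rng)
        np.testing.assert_allclose(avg.values, 45.0)
        ori = sample_stimulus(TrialSpec(1, "catch", 1, 22.5), CONFIGS["ori_avg"], rng)
        np.testing.assert_allclose(ori.values, 22.5)
        coh = sample_stimulus(TrialSpec(1, "catch", -1, 1.0), CONFIGS["motion_coh"], rng)
        assert coh.signal_mask.all()
        np.testing.assert_allclose(coh.values, (-90.0) % 360.0)

    def test_wrapping_into_domain(self, rng):
        trial = TrialSpec(1, "high_noise", side=-1, stimulus_value=120.0)
        motion = sample_stimulus(trial, CONFIGS["motion_avg"], rng)
        assert np.all((motion.values >= 0) & (motion.values < 360))
        ori = sample_stimulus(trial, CONFIGS["ori_avg"], rng)
        assert np.all((ori.values >= 0) & (ori.values < 180))

    def test_out_of_range_values_rejected(self, rng):
        with pytest.raises(ParameterDomainError):
            sample_stimulus(TrialSpec(1, "coherence", 1, 1.4), CONFIGS["motion_coh"], rng)
        with pytest.raises(ParameterDomainError):
            sample_stimulus(TrialSpec(1, "high_noise", 1, -3.0), CONFIGS["motion_avg"], rng)


class TestCriterionPhase:
    def test_always_correct_passes_in_four(self, rng):
        passed, used = run_criterion_phase(lambda es, r: _true_side(es), CONFIGS["motion_avg"], rng)
        assert passed and used == 4

    def test_alternating_never_passes(self, rng):
        state = {"i": 0}

        def alternating(es, r):
            state["i"] += 1
            return _true_side(es) if state["i"] % 2 else -_true_side(es)

        passed, used = run_criterion_phase(alternating, CONFIGS["ori_coh"], rng)
        assert not passed and used == 20


def _true_side(es):
    from equivnoise._circular import circular_mean_offset

    return 1 if circular_mean_offset(es.values, es.period) > 0 else -1


def _clean():
    return TaskOutcome(passed_criterion=True, catch_errors=0, completed=True)


class TestExclusions:
    def test_clean_participant_retained_for_both(self):
        out = {t: _clean() for t in TASK_NAMES}
        out["motion_coh"].coherence_threshold = 0.4
        out["ori_coh"].coherence_threshold = 0.5
        assert apply_exclusions("p1", out).retained_for == "both"

    def test_four_catch_errors_on_motion_excludes(self):
        out = {t: _clean() for t in TASK_NAMES}
        out["motion_avg"] = TaskOutcome(True, catch_errors=4, completed=True)
        assert apply_exclusions("p1", out).retained_for == "neither"

    def test_three_catch_errors_retained(self):
        # 12/15 correct is still above chance at the 5% level
        out = {t: _clean() for t in TASK_NAMES}
        out["motion_avg"] = TaskOutcome(True, catch_errors=3, completed=True)
        assert apply_exclusions("p1", out).retained_for == "both"

    def test_motion_coherence_ceiling_excludes(self):
        out = {t: _clean() for t in TASK_NAMES}
        out["motion_coh"] = TaskOutcome(True, 0, True, coherence_threshold=1.0)
        assert apply_exclusions("p1", out).retained_for == "neither"

    def test_orientation_failure_keeps_motion_analyses(self):
        out = {t: _clean() for t in TASK_NAMES}
        out["ori_coh"] = TaskOutcome(True, 0, True, coherence_threshold=1.0)
        report = apply_exclusions("p1", out)
        assert report.retained_for == "motion"
        assert report.flags["ori_coh"]["threshold_at_ceiling"]

    def test_missing_task_raises(self):
        with pytest.raises(IncompleteInputError):
            apply_exclusions("p1", {"motion_avg": _clean()})


def test_invalid_config_rejected():
    with pytest.raises(Exception):
        TaskConfig("motion", "averaging", fixed_offset_deg=0.0)
    with pytest.raises(Exception):
        TaskConfig("motion", "averaging", staircase_len=0)
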