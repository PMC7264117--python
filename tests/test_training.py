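import numpy as np
import pytest

import gainfield as gf
from gainfield.training import schedule_to_frame


def count_events(schedule, period):
    evs = [e for e in schedule.events if e.period == period]
    fix = [e for e in evs if e.kind == "fixation"]
    sacc = [e for e in evs if e.kind == "saccade" and not e.transition]
    return fix, sacc


class TestMakeSchedule:
    def test_default_protocol_counts(self):
        sched = gf.make_schedule(0)
        periods = {e.period for e in sched.events}
        assert len(periods) == 10 * 21
        fix, sacc = count_events(sched, 0)
        assert len(fix) == 15
        assert len(sacc) == 14

    def test_fixation_targets_are_integers_in_range(self):
        sched = gf.make_schedule(5)
        eyes = [e.eye_start for e in sched.events if e.kind == "fixation"]
        assert all(float(v).is_integer() for v in eyes)
        assert min(eyes) >= -35 and max(eyes) <= 35

    def test_saccade_speed_sets_duration(self):
        # a 40-degree saccade at 400 deg/s lasts 0.1 s
        sched = gf.make_schedule(0)
        for e in sched.events:
            if e.kind == "saccade":
                assert e.duration == pytest.approx(
                    abs(e.eye_end - e.eye_start) / 400.0
                )

    def test_same_seed_reproduces_schedule(self):
        a = schedule_to_frame(gf.make_schedule(9))
        b = schedule_to_frame(gf.make_schedule(9))
        assert a.equals(b)

    def test_events_contiguous_and_alternating(self):
        sched = gf.make_schedule(2)
        prev_end = 0.0
        for e in sched.events:
            assert e.start == pytest.approx(prev_end)
            prev_end = e.end
        for period in range(5):
            evs = [e for e in sched.events
                   if e.period == period and not e.transition]
            kinds = [e.kind for e in evs]
            # strictly alternating once the period is entered
            assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_retinal_coverage_per_epoch(self):
        sched = gf.make_schedule(3)
        seen = {}
        for e in sched.events:
            seen.setdefault(e.retinal_x, set()).add(e.period)
        assert set(seen) == set(np.arange(-10.0, 11.0))
        assert all(len(p) == 10 for p in seen.values())

    def test_fixation_time_accounting(self):
        sched = gf.make_schedule(1)
        for period in range(3):
            fix, sacc = count_events(sched, period)
            total_fix = sum(e.duration for e in fix)
            assert total_fix == pytest.approx(15 * 0.3)
            total_sacc = sum(e.duration for e in sacc)
            expected = sum(abs(e.eye_end - e.eye_start) for e in sacc) / 400.0
            assert total_sacc == pytest.approx(expected)

    def test_nominal_2s_mode_makes_2s_periods(self):
        cfg = gf.TrainingConfig(epochs=1, schedule_mode="nominal_2s")
        sched = gf.make_schedule(0, cfg)
        for period in range(21):
            evs = [e for e in sched.events if e.period == period]
            assert evs[-1].end - evs[0].start == pytest.approx(2.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            gf.make_schedule(0, gf.TrainingConfig(fixations_per_period=0))
        with pytest.raises(ValueError):
            gf.make_schedule(0, gf.TrainingConfig(schedule_mode="bogus"))


class TestNominalDuration:
    @pytest.mark.parametrize(
        "cfg, expected",
        [
            (gf.TrainingConfig(), 420.0),
            (gf.TrainingConfig(epochs=1, retinal_range=(0, 0),
                               presentation_seconds=1.0), 1.0),
            (gf.TrainingConfig(epochs=1), 42.0),
        ],
    )
    def test_arithmetic(self, cfg, expected):
        assert gf.nominal_training_duration(cfg) == expected


class TestScheduleSteps:
    def test_fixation_step_count_and_saccade_endpoint(self):
        cfg = gf.TrainingConfig(epochs=1, retinal_range=(0, 0),
                                fixations_per_period=3)
        sched = gf.make_schedule(0, cfg)
        xs, ys, idx = gf.schedule_steps(sched, dt=0.01)
        # 3 fixations x 30 steps plus rounded-up saccade steps
        fix_steps = sum(
            1 for k in idx if sched.events[k].kind == "fixation"
        )
        assert fix_steps == 90
        # every saccade's last step lands exactly on its target
        for k, ev in enumerate(sched.events):
            if ev.kind == "saccade" and ev.duration > 0:
                last = np.where(idx == k)[0][-1]
                assert ys[last] == ev.eye_end


class TestRunTraining:
    def test_zero_learning_rate_preserves_initial_weights(self):
        layer = gf.default_input_layer()
        net = gf.init_network(4, layer, 30)
        w0 = net.weights.copy()
        cfg = gf.TrainingConfig(epochs=1, retinal_range=(-1, 1),
                                fixations_per_period=4)
        net.learning_rate = 0.0
        gf.run_training(net, layer, gf.make_schedule(4, cfg))
        assert np.array_equal(net.weights, w0)

    def test_learning_restricted_to_fixations(self):
        layer = gf.default_input_layer()
        cfg = gf.TrainingConfig(epochs=1, retinal_range=(0, 0),
                                fixations_per_period=4)
        a = gf.init_network(7, layer, 30)
        b = gf.init_network(7, layer, 30)
        gf.run_training(a, layer, gf.make_schedule(7, cfg))
        gf.run_training(b, layer, gf.make_schedule(7, cfg),
                        learn_during_saccades=False)
        assert not np.array_equal(a.weights, b.weights)
        assert np.allclose(np.linalg.norm(b.weights, axis=1), 1.0, atol=1e-12)

    def test_training_is_deterministic(self):
        layer = gf.default_input_layer()
        cfg = gf.TrainingConfig(epochs=1, retinal_range=(0, 1),
                                fixations_per_period=3)
        runs = []
        for _ in range(2):
            net = gf.init_network(11, layer, 30)
            gf.run_training(net, layer, gf.make_schedule(11, cfg))
            runs.append(net.weights)
        assert np.array_equal(runs[0], runs[1])

    def test_log_shape_and_sparseness_column(self):
        layer = gf.default_input_layer()
        net = gf.init_network(2, layer, 100)
        cfg = gf.TrainingConfig(epochs=2, retinal_range=(-1, 1),
                                fixations_per_period=5)
        _, log = gf.run_training(net, layer, gf.make_schedule(2, cfg))
        assert len(log.frame) == 2 * 3  # periods = epochs x locations
        assert log.frame["mean_sparseness"].between(0, 1).all()

    def test_weight_change_settles_across_epochs(self, trained):
        # per-epoch mean |dw| (3-seed median) trends downward as the map
        # stabilizes: first epoch is the largest, last is below the first,
        # and the linear trend is non-increasing
        per_epoch = []
        for seed in (1, 2, 3):
            _, _, log = trained(seed, 15.0)
            per_epoch.append(log.per_epoch()["mean_abs_dw"].to_numpy())
        med = np.median(np.array(per_epoch), axis=0)
        assert med[0] == med.max()
        assert med[-1] < med[0]
        slope = np.polyfit(np.arange(len(med)), med, 1)[0]
        assert slope <= 0
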