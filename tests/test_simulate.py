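"""Synthetic cohort generator: schedules, hemodynamics, reaction times."""

import numpy as np
import pandas as pd
import pytest

from nirstroop.behavior import paired_t_one_tailed
from nirstroop.simulate import (RTParams, SimulationConfig,
                                default_active_channels,
                                generate_event_schedule, generate_hemo_truth,
                                generate_recording, generate_rt_trials,
                                simulate_subject)


@pytest.fixture
def config():
    return SimulationConfig(seed=11)


class TestEventSchedule:
    def test_default_run_is_48_trials_over_6_minutes(self, config):
        sched = generate_event_schedule(config, "gesture")
        assert len(sched) == 48
        assert config.run_length == 360.0
        assert sched.trials["onset"].max() < 360.0

    def test_one_oddball_per_block_opposite_dominance(self, config):
        sched = generate_event_schedule(config, "color")
        for _, blk in sched.trials.groupby("block_index"):
            odd = blk[blk["is_oddball"]]
            assert len(odd) == 1
            dom = blk["block_dominance"].iloc[0].split("-")[0]
            assert odd["congruency"].iloc[0] != dom

    def test_dominance_balanced_six_six(self, config):
        sched = generate_event_schedule(config, "gesture")
        doms = sched.trials.groupby("block_index")["block_dominance"].first()
        assert (doms == "congruent-dominant").sum() == 6

    def test_same_seed_identical_schedule(self, config):
        a = generate_event_schedule(config, "gesture")
        b = generate_event_schedule(config, "gesture")
        pd.testing.assert_frame_equal(a.trials, b.trials)

    def test_schedule_valid_over_many_seeds(self):
        # design-validity property: the invariants hold for every seed
        for seed in range(1000):
            cfg = SimulationConfig(seed=seed)
            sched = generate_event_schedule(cfg, "gesture")
            sched.validate(cfg)  # raises on violation

    def test_oddball_position_roughly_uniform(self):
        slots = []
        for seed in range(250):
            cfg = SimulationConfig(seed=seed)
            t = generate_event_schedule(cfg, "gesture").trials
            block_start = t["block_index"] * 30.0
            slot = ((t["onset"] - block_start) / cfg.isi).round().astype(int)
            slots.extend(slot[t["is_oddball"]])
        counts = np.bincount(slots, minlength=4)
        # 3000 oddballs over 4 slots: each within 5 sigma of 750
        assert np.all(np.abs(counts - 750) < 5 * np.sqrt(750))

    def test_overfull_block_rejected(self):
        cfg = SimulationConfig(isi=5.0)  # 4 trials x 5 s > 15 s block
        with pytest.raises(ValueError, match="fit"):
            generate_event_schedule(cfg, "gesture")

    def test_gesture_attributes_randomized(self, config):
        t = generate_event_schedule(config, "gesture").trials
        assert t["gesture_type"].nunique() > 1
        assert t["actor_gender"].nunique() == 2


class TestHemoTruth:
    def test_null_config_gives_zero_series(self):
        cfg = SimulationConfig(seed=1, noise_sd=0.0, drift_sd=0.0,
                               systemic={}, active_channels={})
        sched = generate_event_schedule(cfg, "gesture")
        series, amps, _ = generate_hemo_truth(sched, cfg, n_channels=4)
        np.testing.assert_allclose(series.hbo, 0.0, atol=1e-14)
        np.testing.assert_allclose(series.hbr, 0.0, atol=1e-14)
        np.testing.assert_allclose(amps, 0.0)

    def test_noiseless_amplitude_recovered_by_ols(self):
        amp = 0.8
        cfg = SimulationConfig(seed=2, noise_sd=0.0, drift_sd=0.0,
                               systemic={},
                               active_channels={1: ("gesture", amp)})
        sched = generate_event_schedule(cfg, "gesture")
        series, amps, design = generate_hemo_truth(sched, cfg, n_channels=1)
        # independent closed-form OLS on the constructed data
        X = design.values
        beta = np.linalg.lstsq(X, series.hbo[0], rcond=None)[0]
        cond_idx = [i for i, n in enumerate(design.names) if n != "constant"]
        np.testing.assert_allclose(beta[cond_idx], amp, atol=1e-8)
        np.testing.assert_allclose(amps[0, :], amp)

    def test_hbr_mirrors_hbo_at_ratio(self):
        cfg = SimulationConfig(seed=3, noise_sd=0.0, drift_sd=0.0,
                               systemic={},
                               active_channels={1: ("gesture", 1.0)})
        sched = generate_event_schedule(cfg, "gesture")
        series, _, _ = generate_hemo_truth(sched, cfg, n_channels=1)
        np.testing.assert_allclose(series.hbr, -series.hbo / 3.0, atol=1e-12)

    def test_seed_contract_noise_differs_truth_identical(self):
        cfg_a = SimulationConfig(seed=5, active_channels={2: ("color", 1.5)})
        cfg_b = SimulationConfig(seed=6, active_channels={2: ("color", 1.5)})
        sched_a = generate_event_schedule(cfg_a, "color")
        sched_b = generate_event_schedule(cfg_b, "color")
        sa, amps_a, _ = generate_hemo_truth(sched_a, cfg_a, n_channels=3)
        sb, amps_b, _ = generate_hemo_truth(sched_b, cfg_b, n_channels=3)
        assert not np.allclose(sa.hbo, sb.hbo)
        np.testing.assert_allclose(amps_a, amps_b)

    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(seed=9, active_channels={1: ("gesture", 1.0)})
        sched = generate_event_schedule(cfg, "gesture")
        s1, _, _ = generate_hemo_truth(sched, cfg, n_channels=2)
        s2, _, _ = generate_hemo_truth(sched, cfg, n_channels=2)
        assert np.array_equal(s1.hbo, s2.hbo)
        assert np.array_equal(s1.hbr, s2.hbr)


class TestRecording:
    def test_dead_channels_have_outsized_rms(self, config):
        cfg = SimulationConfig(seed=4, dead_channels=(3,))
        sched = generate_event_schedule(cfg, "gesture")
        series, _, _ = generate_hemo_truth(sched, cfg, n_channels=6)
        od = generate_recording(series, cfg, as_intensity=False)
        rms = np.sqrt((od.od.reshape(6, -1) ** 2).mean(axis=1))
        assert rms[2] > 10 * rms.mean() * 0.5  # dead channel dominates
        assert rms[2] == rms.max()

    def test_intensity_positive_and_near_unity(self, config):
        sched = generate_event_schedule(config, "gesture")
        series, _, _ = generate_hemo_truth(sched, config, n_channels=4)
        I = generate_recording(series, config)
        assert np.all(I > 0)
        assert abs(np.log10(I).mean()) < 0.1


class TestReactionTimes:
    def _subject_means(self, delta, sd, n_subjects, seed, mean=1000.0):
        cfg = SimulationConfig(seed=seed)
        cfg.rt_params["gesture"] = RTParams(mean=mean, sd=sd, delta=delta,
                                            between_sd=100.0)
        sched = generate_event_schedule(cfg, "gesture")
        cong, incong = [], []
        for s in range(n_subjects):
            t = generate_rt_trials(sched, cfg, subject=s)
            cong.append(t[t.congruency == "congruent"]["rt_ms"].mean())
            incong.append(t[t.congruency == "incongruent"]["rt_ms"].mean())
        return np.array(cong), np.array(incong)

    def test_zero_delta_zero_expected_difference(self):
        diffs = []
        for seed in range(60):
            c, i = self._subject_means(delta=0.0, sd=80.0, n_subjects=8,
                                       seed=seed)
            diffs.append((i - c).mean())
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 4 * se

    def test_power_at_large_delta(self):
        # delta 100 ms, trial SD 50 ms, 48 trials x 31 subjects: the paired
        # one-tailed test should reject at p < .01 in nearly every replicate
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            c, i = self._subject_means(delta=100.0, sd=50.0, n_subjects=31,
                                       seed=seed)
            _, p, _ = paired_t_one_tailed(i, c)
            rejections += p < 0.01
        assert rejections / n_rep >= 0.95

    def test_accuracy_within_binomial_interval(self):
        cfg = SimulationConfig(seed=21)
        cfg.rt_params["gesture"] = RTParams(accuracy=0.98)
        sched = generate_event_schedule(cfg, "gesture")
        correct = total = 0
        for s in range(40):
            t = generate_rt_trials(sched, cfg, subject=s)
            correct += t["correct"].sum()
            total += len(t)
        phat = correct / total
        ci = 2.576 * np.sqrt(0.98 * 0.02 / total)
        assert abs(phat - 0.98) < ci

    def test_rt_positive_and_deterministic(self):
        cfg = SimulationConfig(seed=13)
        sched = generate_event_schedule(cfg, "color")
        a = generate_rt_trials(sched, cfg, subject=0)
        b = generate_rt_trials(sched, cfg, subject=0)
        assert (a["rt_ms"] > 0).all()
        pd.testing.assert_frame_equal(a, b)


class TestDefaultActiveChannels:
    def test_planted_loci_sit_where_intended(self, layout):
        active = default_active_channels(layout)
        coords = layout.channel_coordinates()
        gesture_right = [ch for ch, specs in active.items()
                         if any(c == "gesture" for c, _ in specs)
                         and coords[ch - 1][0] > 0]
        assert len(gesture_right) == 5
        for ch in gesture_right:
            assert np.linalg.norm(coords[ch - 1] - [70, -30, 10]) < 40

    def test_subject_simulation_carries_planted_truth(self, layout):
        cfg = SimulationConfig(seed=2, n_subjects=1,
                               active_channels=default_active_channels(layout))
        sub = simulate_subject(cfg, 0, layout)
        gesture_truth = sub.truth["gesture"]
        color_truth = sub.truth["color"]
        assert gesture_truth.any()
        # gesture-task effects do not leak into the color run's task columns
        gesture_only = [ch - 1 for ch, specs in cfg.active_channels.items()
                        if all(c == "gesture" for c, _ in specs)]
        assert not color_truth[gesture_only].any()
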