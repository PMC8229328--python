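from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gaitspeed.stats import (build_cohort_grid, correlate, correlation_band,
                             paired_compare, speed_percentiles,
                             summarize_subject, SpeedSummary)


class TestPercentiles:
    def test_constant_distribution(self):
        p = speed_percentiles(np.ones(10))
        assert all(v == 1.0 for v in p.values())

    def test_linear_interpolation_rule(self):
        p = speed_percentiles([0.5, 1.0, 1.5, 2.0])
        assert p["p50"] == pytest.approx(1.25)
        assert p["p25"] == pytest.approx(0.875)
        assert p["max"] == 2.0

    def test_monotone_over_random_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = speed_percentiles(rng.lognormal(0, 0.5, rng.integers(1, 50)))
            vals = [p[k] for k in ("p25", "p50", "p75", "p90", "max")]
            assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestSummarizeSubject:
    @staticmethod
    def _tables():
        strides = pd.DataFrame({
            "t_start": np.arange(40.0), "t_end": np.arange(40.0) + 1,
            "duration": 1.0,
            "speed": [0.8] * 20 + [1.2] * 20,
            "bout_id": [0] * 20 + [1] * 20,
            "state": "ON",
        })
        bouts = pd.DataFrame({
            "bout_id": [0, 1], "t_start": [0.0, 20.0], "t_end": [20.0, 90.0],
            "duration": [20.0, 70.0], "length_class": ["short", "long"],
            "state": "ON",
        })
        return strides, bouts

    def test_wb_stats_per_class(self):
        strides, bouts = self._tables()
        s = summarize_subject(strides, bouts, "ON", subject_id="x")
        assert s.wb_stats[("short", "max")] == pytest.approx(0.8)
        assert s.wb_stats[("long", "max")] == pytest.approx(1.2)
        assert np.isnan(s.wb_stats[("medium", "max")])
        assert "no_medium_bouts" in s.flags

    def test_empty_state_flagged(self):
        strides, bouts = self._tables()
        s = summarize_subject(strides, bouts, "not_ON")
        assert np.isnan(s.percentiles["p50"])
        assert "no_strides_in_state" in s.flags

    def test_speed_floor_removes_static_strides(self):
        strides, bouts = self._tables()
        strides.loc[:4, "speed"] = 0.1
        s = summarize_subject(strides, bouts, "ON")
        assert s.n_strides == 35
        assert s.percentiles["p25"] >= 0.8


def wilcoxon_sign_enumeration(d):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(d, float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    dist = np.array([sum(r for bit, r in zip(bits, ranks) if bit)
                     for bits in product([0, 1], repeat=d.size)])
    return min(1.0, 2 * min((dist <= w_obs).mean(), (dist >= w_obs).mean()))


class TestPairedCompare:
    def test_identical_samples_degenerate(self):
        x = np.arange(6.0)
        res = paired_compare(x, x)
        assert "degenerate_zero_differences" in res.flags
        assert np.isnan(res.p)

    def test_insufficient_pairs(self):
        res = paired_compare([1.0, 2.0], [2.0, 1.0])
        assert "insufficient_n" in res.flags

    @pytest.mark.parametrize("diffs", [
        [0.1, 0.2, 0.4, 0.8, 1.6, 25.6],
        [-0.3, 0.5, 1.0, -2.0, 4.0, -32.0],
        [1.0, 2.0, -3.0, 4.5, 6.0, 7.5, -50.0, 0.25],
    ])
    def test_wilcoxon_matches_sign_enumeration(self, diffs):
        # heavy-tailed differences force the non-parametric branch
        d = np.asarray(diffs)
        y = np.zeros_like(d)
        res = paired_compare(d, y)
        assert res.test_used == "wilcoxon"
        assert res.p == pytest.approx(wilcoxon_sign_enumeration(d), abs=1e-12)

    def test_normal_differences_take_t_test(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 20)
        y = x + rng.normal(0.5, 0.3, 20)
        res = paired_compare(x, y)
        assert res.test_used == "paired_t"
        assert res.p == pytest.approx(sps.ttest_rel(x, y).pvalue)


class TestCorrelate:
    def test_perfect_linearity(self):
        rng = np.random.default_rng(7)
        x = rng.normal(1.0, 0.2, 10)
        res = correlate(x, 2 * x + 1)
        assert res.corr_used == "pearson"
        assert res.r == pytest.approx(1.0)
        assert res.band == "high"
        assert res.r2 == pytest.approx(1.0)

    def test_rank_reversal_spearman(self):
        x = 10.0 ** np.arange(1, 11)  # grossly non-normal
        res = correlate(x, 1 / x)
        assert res.corr_used == "spearman"
        assert res.r == pytest.approx(-1.0)

    def test_spearman_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(0, 1.5, 25)
        y = x ** 1.3 * rng.lognormal(0, 0.4, 25)
        res = correlate(x, y)
        assert res.corr_used == "spearman"
        r_oracle, _ = sps.pearsonr(sps.rankdata(x), sps.rankdata(y))
        assert res.r == pytest.approx(r_oracle, abs=1e-12)

    def test_r2_equals_r_squared_untransformed(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(1.0, 0.2, 27)
            y = 0.8 * x + rng.normal(0, 0.1, 27)
            res = correlate(x, y)
            if res.corr_used == "pearson" and res.transform_applied == "none":
                assert abs(res.r2 - res.r ** 2) < 1e-10

    def test_constant_variable_flagged(self):
        res = correlate(np.ones(10), np.arange(10.0))
        assert "constant_variable" in res.flags
        assert np.isnan(res.r)

    def test_band_breakpoints(self):
        assert correlation_band(0.49) == "low"
        assert correlation_band(0.5) == "moderate"
        assert correlation_band(0.7) == "moderate"
        assert correlation_band(0.71) == "high"
        assert correlation_band(-0.8) == "high"   # banding uses |r|

    def test_estimator_consistency(self):
        """Mean estimated correlation over replicates approaches the
        population value (bivariate normal, rho = 0.6, n = 27)."""
        rng = np.random.default_rng(11)
        cov = [[1, 0.6], [0.6, 1]]
        rs = []
        for _ in range(2000):
            z = rng.multivariate_normal([0, 0], cov, 27)
            rs.append(correlate(z[:, 0], z[:, 1]).r)
        assert np.mean(rs) == pytest.approx(0.6, abs=0.03)


def _toy_cohort(n=6):
    """Hand-built cohort where home ON max equals lab fast speed exactly."""
    caps = np.linspace(0.8, 1.5, n)
    lab_rows, summaries = [], []
    for i, c in enumerate(caps):
        sid = f"s{i}"
        for task, state, v in [("straight_normal", "ON", c),
                               ("straight_fast", "ON", 1.25 * c),
                               ("circular_left", "ON", 0.7 * c),
                               ("straight_normal", "OFF", 0.95 * c),
                               ("circular_left", "OFF", 0.6 * c)]:
            lab_rows.append({"subject_id": sid, "task": task,
                             "med_state": state, "mean_speed": v})
        for state in ("ON", "not_ON"):
            pct = {"p25": 0.5 * c, "p50": 0.6 * c, "p75": 0.8 * c,
                   "p90": c, "max": 1.25 * c}
            wb = {(cls, stat): 0.7 * c for cls in ("short", "medium", "long")
                  for stat in ("p25", "p50", "max")}
            summaries.append(SpeedSummary(subject_id=sid, state=state,
                                          percentiles=pct, wb_stats=wb))
    return pd.DataFrame(lab_rows), summaries


class TestCohortGrid:
    def test_exact_identity_cell(self):
        lab, summaries = _toy_cohort()
        res = build_cohort_grid(lab, summaries)
        g = res.lab_home_grid
        cell = g[(g.lab_state == "ON") & (g.home_state == "ON")
                 & (g.task == "straight_fast") & (g.metric == "max")]
        assert cell["r"].iloc[0] == pytest.approx(1.0)

    def test_grid_shape_mirrors_report_layout(self):
        lab, summaries = _toy_cohort()
        res = build_cohort_grid(lab, summaries)
        g = res.lab_home_grid
        on_on = g[(g.lab_state == "ON") & (g.home_state == "ON")]
        # 5 percentile rows x 3 tasks per state pairing
        assert len(on_on) == 15
        off = g[(g.lab_state == "OFF") & (g.home_state == "not_ON")]
        assert set(off["task"]) == {"straight_normal", "circular"}  # no fast OFF
        wb = res.wb_grid
        assert len(wb[(wb.lab_state == "ON")]) == 3 * 3 * 3

    def test_cohort_of_two_flagged_insufficient(self):
        lab, summaries = _toy_cohort(n=2)
        res = build_cohort_grid(lab, summaries)
        assert "insufficient_cohort" in res.flags
        assert res.lab_home_grid["flags"].str.contains("insufficient_n").all()

    def test_report_roundtrip(self, tmp_path):
        from gaitspeed.io import write_report
        lab, summaries = _toy_cohort()
        res = build_cohort_grid(lab, summaries)
        write_report(res, tmp_path / "report.json", tmp_path / "report.csv")
        flat = pd.read_csv(tmp_path / "report.csv")
        assert {"task", "metric", "comparison_p", "r", "r2"} <= set(flat.columns)
        assert len(flat) == len(res.lab_home_grid) + len(res.wb_grid)

    def test_empty_grid_writes_header_only(self, tmp_path):
        from gaitspeed.io import write_report
        from gaitspeed.stats import CohortResult
        res = CohortResult(lab_home_grid=pd.DataFrame(), wb_grid=pd.DataFrame(),
                           state_comparison=pd.DataFrame(), clinical_corr=None,
                           n_subjects=0)
        write_report(res, tmp_path / "r.json", tmp_path / "r.csv")
        flat = pd.read_csv(tmp_path / "r.csv")
        assert len(flat) == 0
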