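"""Per-subject speed summaries and the group-level lab-vs-home statistics.

Two complementary views of home walking are summarized per subject and
medication state: the stride-level speed distribution (25th/50th/75th/90th
percentile and maximum) and per-bout mean speeds stratified by bout-length
class (25th/50th percentile and maximum of the bout means).  Group-level
comparisons are normality-gated: Shapiro-Wilk selects paired t vs Wilcoxon
signed-rank for paired contrasts and Pearson vs Spearman for correlations;
correlation magnitudes are banded at 0.5 and 0.7, and R^2 comes from a
straight-line fit of home on lab with a log transform of any non-normal
variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .constants import (MIN_STRIDE_SPEED, PERCENTILE_KEYS, PERCENTILE_Q,
                        WB_CLASSES, WB_STAT_KEYS)

LAB_TASKS = ("straight_normal", "straight_fast", "circular")


# --------------------------------------------------------------------------- #
# per-subject summaries
# --------------------------------------------------------------------------- #

@dataclass
class SpeedSummary:
    """Distributional summary of one subject's home gait speed in one state."""

    subject_id: str
    state: str                                  # ON | not_ON
    percentiles: dict = field(default_factory=dict)   # p25..max -> m/s or nan
    wb_stats: dict = field(default_factory=dict)      # (class, stat) -> m/s or nan
    n_strides: int = 0
    n_bouts: dict = field(default_factory=dict)       # class -> count
    flags: set = field(default_factory=set)


def speed_percentiles(speeds: np.ndarray) -> dict:
    """Percentiles by linear interpolation on the sorted sample."""
    speeds = np.asarray(speeds, float)
    if speeds.size == 0:
        return {k: float("nan") for k in PERCENTILE_KEYS}
    vals = np.percentile(speeds, [PERCENTILE_Q[k] for k in PERCENTILE_KEYS])
    return dict(zip(PERCENTILE_KEYS, (float(v) for v in vals)))


def summarize_subject(strides: pd.DataFrame, bouts: pd.DataFrame, state: str,
                      subject_id: str = "", min_speed: float = MIN_STRIDE_SPEED,
                      ) -> SpeedSummary:
    """Build one subject-state SpeedSummary.

    ``strides`` and ``bouts`` must be state-labeled (``state`` column) and
    carry ``bout_id``.  The stride-speed floor removes static periods from
    all speed summaries; bout membership is decided before filtering.  Bout
    means are recomputed over the retained strides of each bout.
    """
    flags: set = set()
    s = strides[strides["state"] == state]
    s = s[s["speed"] >= min_speed]
    pct = speed_percentiles(s["speed"].to_numpy())
    if s.empty:
        flags.add("no_strides_in_state")

    wb: dict = {}
    n_bouts: dict = {}
    b = bouts[(bouts["state"] == state) & (bouts["length_class"].isin(WB_CLASSES))]
    retained = strides[strides["speed"] >= min_speed]
    bout_means = retained.groupby("bout_id")["speed"].mean()
    for cls in WB_CLASSES:
        ids = b.loc[b["length_class"] == cls, "bout_id"]
        means = bout_means.reindex(ids).dropna().to_numpy()
        n_bouts[cls] = int(means.size)
        if means.size == 0:
            for stat in WB_STAT_KEYS:
                wb[(cls, stat)] = float("nan")
            flags.add(f"no_{cls}_bouts")
        else:
            vals = np.percentile(means, [PERCENTILE_Q[k] for k in WB_STAT_KEYS])
            for stat, v in zip(WB_STAT_KEYS, vals):
                wb[(cls, stat)] = float(v)
    return SpeedSummary(subject_id=subject_id, state=state, percentiles=pct,
                        wb_stats=wb, n_strides=int(len(s)), n_bouts=n_bouts,
                        flags=flags)


# --------------------------------------------------------------------------- #
# paired comparison and correlation
# --------------------------------------------------------------------------- #

@dataclass
class PairedComparison:
    test_used: str | None = None     # paired_t | wilcoxon
    p: float = float("nan")
    normality_p: float = float("nan")
    n: int = 0
    flags: set = field(default_factory=set)


@dataclass
class CorrelationResult:
    corr_used: str | None = None     # pearson | spearman
    r: float = float("nan")
    p: float = float("nan")
    band: str | None = None          # low | moderate | high
    r2: float = float("nan")
    transform_applied: str = "none"  # none | log
    n: int = 0
    flags: set = field(default_factory=set)


def correlation_band(r: float) -> str:
    """Band |r| at the conventional 0.5 / 0.7 cut-offs."""
    a = abs(r)
    if a < 0.5:
        return "low"
    if a <= 0.7:
        return "moderate"
    return "high"


def _complete_cases(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def _is_normal(v: np.ndarray, alpha: float) -> tuple[bool, float]:
    """Shapiro-Wilk normality gate; a constant sample is treated as non-normal."""
    if np.ptp(v) == 0:
        return False, float("nan")
    _, p = sps.shapiro(v)
    return p > alpha, float(p)


def paired_compare(x, y, alpha: float = 0.05) -> PairedComparison:
    """Paired two-sided comparison, test choice gated on the differences.

    Shapiro-Wilk on x - y at ``alpha`` selects the paired t-test (normal) or
    the Wilcoxon signed-rank test (otherwise, exact where sample size and
    ties permit).  Fewer than 3 complete pairs, or all-zero differences, are
    flagged instead of tested.
    """
    x, y = _complete_cases(x, y)
    res = PairedComparison(n=int(x.size))
    if x.size < 3:
        res.flags.add("insufficient_n")
        return res
    d = x - y
    if np.all(d == 0):
        res.flags.add("degenerate_zero_differences")
        return res
    normal, p_norm = _is_normal(d, alpha)
    res.normality_p = p_norm
    if np.ptp(d) == 0:
        res.flags.add("constant_differences")
    if normal:
        res.test_used = "paired_t"
        res.p = float(sps.ttest_rel(x, y).pvalue)
    else:
        res.test_used = "wilcoxon"
        res.p = float(sps.wilcoxon(x, y, zero_method="wilcox",
                                   alternative="two-sided").pvalue)
    return res


def correlate(x, y, alpha: float = 0.05, transform: str = "log") -> CorrelationResult:
    """Normality-gated correlation of lab (x) against home (y), with R^2.

    Pearson if both variables pass Shapiro-Wilk at ``alpha``, else Spearman.
    R^2 is the squared correlation of a straight-line fit of y on x after
    log-transforming any variable that failed normality (speeds are
    positive); a non-positive value blocks the transform and is flagged.
    """
    x, y = _complete_cases(x, y)
    res = CorrelationResult(n=int(x.size))
    if x.size < 3:
        res.flags.add("insufficient_n")
        return res
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        res.flags.add("constant_variable")
        return res
    x_normal, _ = _is_normal(x, alpha)
    y_normal, _ = _is_normal(y, alpha)
    if x_normal and y_normal:
        res.corr_used = "pearson"
        r, p = sps.pearsonr(x, y)
    else:
        res.corr_used = "spearman"
        r, p = sps.spearmanr(x, y)
    res.r, res.p = float(r), float(p)
    res.band = correlation_band(res.r)

    xt, yt, applied = x, y, "none"
    if transform == "log":
        for_transform = []
        if not x_normal:
            for_transform.append("x")
        if not y_normal:
            for_transform.append("y")
        if for_transform and (np.all(x > 0) if "x" in for_transform else True) \
                and (np.all(y > 0) if "y" in for_transform else True):
            if "x" in for_transform:
                xt = np.log(x)
            if "y" in for_transform:
                yt = np.log(y)
            if for_transform:
                applied = "log"
        elif for_transform:
            res.flags.add("nonpositive_values_block_transform")
    fit = sps.linregress(xt, yt)
    res.r2 = float(fit.rvalue ** 2)
    res.transform_applied = applied
    return res


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; the default analysis applies none)."""
    p = np.asarray(pvals, float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


# --------------------------------------------------------------------------- #
# cohort grid
# --------------------------------------------------------------------------- #

@dataclass
class CohortResult:
    """All group-level outputs: lab-vs-home grids, state contrasts, clinical
    correlations, and the subject-level summaries they were computed from."""

    lab_home_grid: pd.DataFrame
    wb_grid: pd.DataFrame
    state_comparison: pd.DataFrame
    clinical_corr: pd.DataFrame | None
    n_subjects: int
    flags: set = field(default_factory=set)

    def flat_table(self) -> pd.DataFrame:
        cols = ["lab_state", "home_state", "task", "metric",
                "comparison_p", "r", "corr_p", "r2"]
        parts = [self.lab_home_grid, self.wb_grid]
        parts = [p for p in parts if len(p)]
        if not parts:
            return pd.DataFrame(columns=cols)
        flat = pd.concat(parts, ignore_index=True)
        return flat[[c for c in cols if c in flat.columns]
                    + [c for c in flat.columns if c not in cols]]

    def to_json_dict(self) -> dict:
        def df_records(df):
            return [] if df is None else df.replace({np.nan: None}).to_dict("records")
        return {
            "n_subjects": self.n_subjects,
            "flags": sorted(self.flags),
            "lab_home_grid": df_records(self.lab_home_grid),
            "wb_grid": df_records(self.wb_grid),
            "state_comparison": df_records(self.state_comparison),
            "clinical_correlations": df_records(self.clinical_corr),
        }


def _cell(lab_vec, home_vec, alpha, transform) -> dict:
    cmp_res = paired_compare(lab_vec, home_vec, alpha=alpha)
    cor = correlate(lab_vec, home_vec, alpha=alpha, transform=transform)
    return {
        "comparison_p": cmp_res.p, "comparison_test": cmp_res.test_used,
        "r": cor.r, "corr_p": cor.p, "corr_used": cor.corr_used,
        "band": cor.band, "r2": cor.r2, "transform": cor.transform_applied,
        "n": cor.n, "flags": ";".join(sorted(cmp_res.flags | cor.flags)),
    }


def _lab_task_means(lab_means: pd.DataFrame) -> pd.DataFrame:
    """Pivot per-trial means to subject x (task, state); the two circular
    directions are averaged into a single circular task."""
    lm = lab_means.copy()
    lm["task"] = lm["task"].replace({"circular_left": "circular",
                                     "circular_right": "circular"})
    return lm.pivot_table(index="subject_id", columns=["task", "med_state"],
                          values="mean_speed", aggfunc="mean")


def summaries_frame(summaries: list[SpeedSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"subject_id": s.subject_id, "state": s.state, **s.percentiles}
        for (cls, stat), v in s.wb_stats.items():
            row[f"wb_{cls}_{stat}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def build_cohort_grid(lab_means: pd.DataFrame, summaries: list[SpeedSummary],
                      clinical: pd.DataFrame | None = None, alpha: float = 0.05,
                      transform: str = "log",
                      mt_correction: str = "none") -> CohortResult:
    """Assemble the full lab-vs-home comparison grids.

    Parameters
    ----------
    lab_means : DataFrame with columns subject_id, task, med_state, mean_speed
        Steady-state trial means (fast pace typically available in ON only).
    summaries : per-subject SpeedSummary for both home states.
    clinical : optional DataFrame with subject_id, updrs3_on, updrs3_off and
        item30_on/item30_off gait-item scores.

    Produces same-state grids (lab ON vs home ON, lab OFF vs home not-ON),
    opposite-state grids, WB-stratified grids (same-state), per-variable
    ON-vs-OFF paired contrasts, and clinical-score correlations.  Cells with
    fewer than 3 complete pairs are emitted flagged rather than dropped.
    """
    lab = _lab_task_means(lab_means)
    summ = summaries_frame(summaries)
    subjects = sorted(set(lab.index) & set(summ["subject_id"]))
    n_subjects = len(subjects)
    flags = set()
    if n_subjects < 3:
        flags.add("insufficient_cohort")

    home = {state: summ[summ["state"] == state].set_index("subject_id")
            .reindex(subjects) for state in ("ON", "not_ON")}
    lab = lab.reindex(subjects)

    def lab_vec(task, state):
        if (task, state) in lab.columns:
            return lab[(task, state)].to_numpy()
        return np.full(n_subjects, np.nan)

    state_pairs = [("ON", "ON"), ("OFF", "not_ON"), ("ON", "not_ON"), ("OFF", "ON")]
    grid_rows, wb_rows = [], []
    for lab_state, home_state in state_pairs:
        hs = home[home_state]
        for task in LAB_TASKS:
            lv = lab_vec(task, lab_state)
            if np.all(np.isnan(lv)):
                continue
            for key in PERCENTILE_KEYS:
                cell = _cell(lv, hs[key].to_numpy(), alpha, transform)
                grid_rows.append({"lab_state": lab_state, "home_state": home_state,
                                  "task": task, "metric": key, **cell})
            if (lab_state, home_state) in (("ON", "ON"), ("OFF", "not_ON")):
                for cls in WB_CLASSES:
                    for stat in WB_STAT_KEYS:
                        col = f"wb_{cls}_{stat}"
                        hv = hs[col].to_numpy() if col in hs else np.full(n_subjects, np.nan)
                        cell = _cell(lv, hv, alpha, transform)
                        wb_rows.append({"lab_state": lab_state, "home_state": home_state,
                                        "task": task, "metric": f"{cls}_{stat}", **cell})

    lab_home_grid = pd.DataFrame(grid_rows)
    wb_grid = pd.DataFrame(wb_rows)

    # ON vs OFF / not-ON contrasts per variable
    sc_rows = []
    for task in LAB_TASKS:
        c = paired_compare(lab_vec(task, "ON"), lab_vec(task, "OFF"), alpha=alpha)
        sc_rows.append({"domain": "lab", "variable": task, "p": c.p,
                        "test_used": c.test_used, "n": c.n,
                        "flags": ";".join(sorted(c.flags))})
    for key in PERCENTILE_KEYS:
        c = paired_compare(home["ON"][key].to_numpy(),
                           home["not_ON"][key].to_numpy(), alpha=alpha)
        sc_rows.append({"domain": "home", "variable": key, "p": c.p,
                        "test_used": c.test_used, "n": c.n,
                        "flags": ";".join(sorted(c.flags))})
    state_comparison = pd.DataFrame(sc_rows)

    clinical_corr = None
    if clinical is not None:
        cl = clinical.set_index("subject_id").reindex(subjects)
        cl_rows = []
        pairs = [("updrs3_on", "ON"), ("item30_on", "ON"),
                 ("updrs3_off", "not_ON"), ("item30_off", "not_ON")]
        for score_col, home_state in pairs:
            if score_col not in cl.columns:
                continue
            for key in PERCENTILE_KEYS:
                cor = correlate(cl[score_col].to_numpy(),
                                home[home_state][key].to_numpy(),
                                alpha=alpha, transform="none")
                cl_rows.append({"score": score_col, "home_state": home_state,
                                "metric": key, "r": cor.r, "p": cor.p,
                                "corr_used": cor.corr_used, "band": cor.band,
                                "n": cor.n, "flags": ";".join(sorted(cor.flags))})
        clinical_corr = pd.DataFrame(cl_rows)

    if mt_correction == "benjamini_hochberg":
        for df in (lab_home_grid, wb_grid):
            if len(df):
                ok = df["corr_p"].notna()
                df.loc[ok, "corr_p_adj"] = benjamini_hochberg(df.loc[ok, "corr_p"].to_numpy())

    return CohortResult(lab_home_grid=lab_home_grid, wb_grid=wb_grid,
                        state_comparison=state_comparison,
                        clinical_corr=clinical_corr,
                        n_subjects=n_subjects, flags=flags)
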