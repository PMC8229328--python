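#!/usr/bin/env python
"""Build the lab-vs-home correlation grids and clinical-score correlations.

Produces the report tables (one row per lab task x home metric with the
paired-comparison p, correlation r and its p, band, and R^2), for same-state
and opposite-state pairings and for the walking-bout-stratified view, plus
the UPDRS correlations.  Writes results/lab_home_grid.csv, results/wb_grid.csv,
results/clinical_correlations.csv and results/report.json.
"""

import importlib.util
from pathlib import Path

from gaitspeed.io import write_report
from gaitspeed.pipeline import analyze_cohort, analyze_home_day, lab_means_from_stride_table

ROOT = Path(__file__).resolve().parents[1]
_spec = importlib.util.spec_from_file_location(
    "state_comparison", ROOT / "analysis" / "03_state_comparison.py")
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)


def main() -> None:
    lab, home, diaries, clinical = _mod.load_cohort()
    res = analyze_cohort(lab, home, diaries, clinical=clinical)
    out = ROOT / "results"
    write_report(res, out / "report.json", out / "lab_home_grid.csv")
    res.wb_grid.to_csv(out / "wb_grid.csv", index=False)
    if res.clinical_corr is not None:
        res.clinical_corr.to_csv(out / "clinical_correlations.csv", index=False)

    g = res.lab_home_grid
    on = g[(g.lab_state == "ON") & (g.home_state == "ON")
           & (g.task == "straight_fast")].set_index("metric")["r"]
    off = g[(g.lab_state == "OFF") & (g.home_state == "not_ON")
            & (g.task == "straight_normal")].set_index("metric")["r"]
    print("lab fast (ON) vs home ON percentiles:   "
          + "  ".join(f"{k}={on[k]:.2f}" for k in ("p25", "p50", "p75", "p90", "max")))
    print("lab normal (OFF) vs home not-ON:        "
          + "  ".join(f"{k}={off[k]:.2f}" for k in ("p25", "p50", "p75", "p90", "max")))
    print("(single-cohort correlations are noisy at n=27; the tail-linkage "
          "ordering is asserted over 200 cohorts in the test suite)")

    # per-state percentile overview figure (scratch: binary output)
    summaries = []
    for sid, grp in home.groupby("subject_id"):
        day = analyze_home_day(grp.drop(columns=["subject_id"]),
                               diaries.get(sid, []), subject_id=sid)
        summaries.extend(day["summaries"].values())
    fig_dir = ROOT / "scratch" / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    from gaitspeed.plotting import plot_state_percentiles
    plot_state_percentiles(summaries, fig_dir / "state_percentiles.png")
    print(f"-> {out / 'report.json'}, grids and clinical correlations in {out}")


if __name__ == "__main__":
    main()
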