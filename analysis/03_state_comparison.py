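#!/usr/bin/env python
"""Compare medication states: lab ON vs OFF, home ON vs not-ON.

Reads the simulated cohort from results/cohort/ (run 02_simulate_cohort.py
first, or this script regenerates it with the same seed), runs the pipeline,
and writes per-variable paired comparisons to results/state_comparison.csv.
"""

import subprocess
import sys
from pathlib import Path

import pandas as pd

from gaitspeed.pipeline import analyze_cohort

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"


def load_cohort():
    if not (COHORT / "home_strides.csv").exists():
        subprocess.run([sys.executable, str(ROOT / "analysis" / "02_simulate_cohort.py")],
                       check=True)
    lab = pd.read_csv(COHORT / "lab_strides.csv")
    home = pd.read_csv(COHORT / "home_strides.csv")
    diaries = {sid: grp["timestamp"].tolist()
               for sid, grp in pd.read_csv(COHORT / "diaries.csv").groupby("subject_id")}
    clinical = pd.read_csv(COHORT / "clinical.csv")
    return lab, home, diaries, clinical


def main() -> None:
    lab, home, diaries, clinical = load_cohort()
    res = analyze_cohort(lab, home, diaries, clinical=clinical)
    sc = res.state_comparison
    sc.to_csv(ROOT / "results" / "state_comparison.csv", index=False)
    print(sc.to_string(index=False))
    sig = sc[sc["p"] < 0.05]
    print(f"\n{len(sig)}/{len(sc)} variables separate the medication states "
          f"at p < 0.05 in this cohort")
    print(f"-> {ROOT / 'results' / 'state_comparison.csv'}")


if __name__ == "__main__":
    main()
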