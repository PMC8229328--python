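"""Walking-bout segmentation, bout-length classes, stride filters, and
medication-state labelling from the intake diary.

Bouts are maximal runs of consecutive strides whose inter-stride gap stays
below a threshold; their durations are classed as short (15-30 s), medium
(>30-60 s) or long (>60 s), with bouts under 15 s excluded from summaries.
Medication states are windows anchored on diary intakes: ON is 60-180 min
after an intake, not-ON is 30 min before to 30 min after; everything else is
unlabeled.  All labeled intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (BOUT_MEDIUM_MAX_S, BOUT_SHORT_MAX_S, BOUT_SHORT_MIN_S,
                        MIN_STRIDE_SPEED, NOTON_WINDOW_S, ON_WINDOW_S)
from .io import IntakeEvent

STRIDE_COLUMNS = ["t_start", "t_end", "duration", "speed"]


# --------------------------------------------------------------------------- #
# bout segmentation and classification
# --------------------------------------------------------------------------- #

def classify_bout_duration(duration) -> np.ndarray:
    """Class labels for bout durations (s); edges follow the printed intervals:
    <15 excluded, [15, 30] short, (30, 60] medium, (60, inf) long."""
    d = np.asarray(duration, dtype=float)
    return np.select(
        [d < BOUT_SHORT_MIN_S, d <= BOUT_SHORT_MAX_S, d <= BOUT_MEDIUM_MAX_S],
        ["excluded_short", "short", "medium"],
        default="long",
    )


def segment_bouts(strides: pd.DataFrame, max_gap: float = 3.0):
    """Group time-ordered strides into walking bouts.

    A new bout starts whenever the gap from the previous stride's end to the
    next stride's start exceeds ``max_gap`` seconds.  Returns
    ``(bouts, strides)`` where ``strides`` is a copy carrying a ``bout_id``
    column and ``bouts`` has one row per bout with duration, class and the
    mean speed over all its strides.
    """
    strides = strides.sort_values("t_start", kind="stable").reset_index(drop=True).copy()
    if len(strides) == 0:
        bouts = pd.DataFrame(columns=["bout_id", "t_start", "t_end", "duration",
                                      "n_strides", "mean_speed", "length_class"])
        strides["bout_id"] = pd.Series(dtype=int)
        return bouts, strides
    gap = strides["t_start"].to_numpy()[1:] - strides["t_end"].to_numpy()[:-1]
    bout_id = np.concatenate([[0], np.cumsum(gap > max_gap)])
    strides["bout_id"] = bout_id
    bouts = strides.groupby("bout_id").agg(
        t_start=("t_start", "first"),
        t_end=("t_end", "last"),
        n_strides=("speed", "size"),
        mean_speed=("speed", "mean"),
    ).reset_index()
    bouts["duration"] = bouts["t_end"] - bouts["t_start"]
    bouts["length_class"] = classify_bout_duration(bouts["duration"])
    return bouts[["bout_id", "t_start", "t_end", "duration",
                  "n_strides", "mean_speed", "length_class"]], strides


def filter_strides(strides: pd.DataFrame, min_speed: float = MIN_STRIDE_SPEED) -> pd.DataFrame:
    """Drop strides slower than ``min_speed`` (static periods mislabeled as gait).

    Applied to speed summaries only; bout segmentation itself runs on the
    unfiltered sequence.  The boundary is kept (the rule is "less than").
    """
    return strides[strides["speed"] >= min_speed].copy()


# --------------------------------------------------------------------------- #
# medication-state timeline
# --------------------------------------------------------------------------- #

def _merge(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out: list[list[float]] = []
    for a, b in sorted(intervals):
        if b <= a:
            continue
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def _subtract(keep: list[tuple[float, float]],
              cut: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Set difference keep \\ cut on half-open intervals (both pre-merged)."""
    out = []
    for a, b in keep:
        pieces = [(a, b)]
        for c, d in cut:
            nxt = []
            for x, y in pieces:
                if d <= x or c >= y:
                    nxt.append((x, y))
                    continue
                if x < c:
                    nxt.append((x, c))
                if d < y:
                    nxt.append((d, y))
            pieces = nxt
        out.extend(pieces)
    return _merge(out)


@dataclass
class StateTimeline:
    """Disjoint ON / not-ON intervals (half-open, seconds) over a recording."""

    on_intervals: list[tuple[float, float]] = field(default_factory=list)
    noton_intervals: list[tuple[float, float]] = field(default_factory=list)

    def label(self, t: float) -> str:
        return str(self.label_array(np.array([t]))[0])

    def label_array(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, "unlabeled", dtype=object)
        for label, ivs in (("ON", self.on_intervals), ("not_ON", self.noton_intervals)):
            for a, b in ivs:
                out[(t >= a) & (t < b)] = label
        return out.astype(str)


def build_state_timeline(intakes, on_window_s=ON_WINDOW_S,
                         noton_window_s=NOTON_WINDOW_S,
                         overlap_policy: str = "noton_wins") -> StateTimeline:
    """Construct the per-intake ON / not-ON windows and resolve overlaps.

    ``intakes`` is a sequence of IntakeEvent or plain times in seconds.  With
    the default policy, not-ON wins where windows from different doses collide
    (proximity to an intake means the drug effect is not yet established);
    ``on_wins`` and ``drop`` are the alternatives.
    """
    times = sorted(e.time if isinstance(e, IntakeEvent) else float(e) for e in intakes)
    on_raw = _merge([(t + on_window_s[0], t + on_window_s[1]) for t in times])
    noton_raw = _merge([(t + noton_window_s[0], t + noton_window_s[1]) for t in times])
    if overlap_policy == "noton_wins":
        on, noton = _subtract(on_raw, noton_raw), noton_raw
    elif overlap_policy == "on_wins":
        on, noton = on_raw, _subtract(noton_raw, on_raw)
    elif overlap_policy == "drop":
        on = _subtract(on_raw, noton_raw)
        noton = _subtract(noton_raw, on_raw)
    else:
        raise ValueError(f"unknown overlap_policy {overlap_policy!r}")
    return StateTimeline(on_intervals=on, noton_intervals=noton)


def assign_states(table: pd.DataFrame, timeline: StateTimeline) -> pd.DataFrame:
    """Label bouts (or strides) with the state containing their midpoint.

    The midpoint rule is deterministic and independent of row order; rows
    whose midpoint falls in no labeled interval become ``unlabeled``.
    """
    out = table.copy()
    if len(out) == 0:
        out["state"] = pd.Series(dtype=str)
        return out
    mid = 0.5 * (out["t_start"].to_numpy() + out["t_end"].to_numpy())
    out["state"] = timeline.label_array(mid)
    return out
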