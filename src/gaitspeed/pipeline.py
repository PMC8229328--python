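"""End-to-end orchestration: raw streams or stride tables in, cohort report out."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import bouts as bt
from . import stats as st
from . import stride as sd
from .config import PipelineConfig
from .io import IMURecording, IntakeEvent

log = logging.getLogger("gaitspeed")


def estimate_recording(rec: IMURecording, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Raw IMU stream -> per-stride table (io_core + stride_speed)."""
    cfg = cfg or PipelineConfig()
    rec.validate()
    mask = sd.detect_still(rec, gyro_thresh=cfg.gyro_thresh,
                           accel_band=cfg.accel_band, min_still=cfg.min_still_s)
    strides = sd.estimate_strides(rec, mask,
                                  max_stride_duration=cfg.max_stride_duration_s)
    log.info("detected %d still intervals, %d strides", len(mask.intervals), len(strides))
    return sd.strides_to_frame(strides)


def analyze_home_day(strides: pd.DataFrame, intakes: list[IntakeEvent] | list[float],
                     cfg: PipelineConfig | None = None, subject_id: str = "") -> dict:
    """Stride table + diary -> bouts, states, and both per-state summaries.

    Returns a dict with the labeled stride/bout tables, the state timeline,
    per-state SpeedSummary objects, and the filter bookkeeping (how many
    strides fell below the speed floor, how many bouts were excluded short).
    """
    cfg = cfg or PipelineConfig()
    on_w = tuple(60.0 * m for m in cfg.on_window_min)
    noton_w = tuple(60.0 * m for m in cfg.noton_window_min)
    timeline = bt.build_state_timeline(intakes, on_window_s=on_w,
                                       noton_window_s=noton_w,
                                       overlap_policy=cfg.overlap_policy)
    bouts, strides = bt.segment_bouts(strides, max_gap=cfg.max_gap_s)
    bouts = bt.assign_states(bouts, timeline)
    strides = bt.assign_states(strides, timeline)
    n_slow = int((strides["speed"] < cfg.min_speed_ms).sum())
    n_excluded = int((bouts["length_class"] == "excluded_short").sum())
    log.info("%s: %d strides below %.2f m/s removed from summaries; "
             "%d/%d bouts shorter than %.0f s excluded",
             subject_id or "day", n_slow, cfg.min_speed_ms,
             n_excluded, len(bouts), cfg.min_bout_s)
    summaries = {
        state: st.summarize_subject(strides, bouts, state, subject_id=subject_id,
                                    min_speed=cfg.min_speed_ms)
        for state in ("ON", "not_ON")
    }
    return {"strides": strides, "bouts": bouts, "timeline": timeline,
            "summaries": summaries, "n_slow_strides": n_slow,
            "n_excluded_bouts": n_excluded}


def lab_means_from_stride_table(lab_strides: pd.DataFrame,
                                cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-trial steady-state means from a long stride-speed table.

    Expects columns subject_id, task, med_state, speed (one row per gait
    cycle, in trial order); applies the trim-two-cycles-per-end rule.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    for (sid, task, state), grp in lab_strides.groupby(
            ["subject_id", "task", "med_state"], sort=True):
        mean, n_trimmed, flags = sd.steady_state_mean(
            grp["speed"].to_numpy(), n_trim=cfg.n_trim_lab)
        rows.append({"subject_id": sid, "task": task, "med_state": state,
                     "mean_speed": mean, "n_strides": len(grp),
                     "n_trimmed": n_trimmed, "flags": ";".join(sorted(flags))})
    return pd.DataFrame(rows)


def analyze_cohort(lab_strides: pd.DataFrame, home_strides: pd.DataFrame,
                   diaries: dict, clinical: pd.DataFrame | None = None,
                   cfg: PipelineConfig | None = None) -> st.CohortResult:
    """Full group-level analysis from stride tables.

    ``home_strides`` must carry subject_id plus the stride truth/estimate
    columns (t_start, t_end, duration, speed); ``diaries`` maps subject_id to
    intake events (seconds or IntakeEvent).
    """
    cfg = cfg or PipelineConfig()
    lab_means = lab_means_from_stride_table(lab_strides, cfg)
    summaries = []
    for sid, grp in home_strides.groupby("subject_id", sort=True):
        day = analyze_home_day(grp.drop(columns=["subject_id"]),
                               diaries.get(sid, []), cfg, subject_id=sid)
        summaries.extend(day["summaries"].values())
    return st.build_cohort_grid(lab_means, summaries, clinical=clinical,
                                alpha=cfg.alpha, transform=cfg.transform,
                                mt_correction=cfg.mt_correction)
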