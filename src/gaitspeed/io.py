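"""Data types, unit normalization and readers/writers.

All internal times are seconds relative to recording start; all internal
units are SI (m/s^2 for acceleration, rad/s for angular rate).  The IMU
stream dialect is delimited text with a mandatory header
``time,ax,ay,az,gx,gy,gz``; input units are declared by the caller (or a
config file), defaulting to SI.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import G

IMU_COLUMNS = ["time", "ax", "ay", "az", "gx", "gy", "gz"]


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #

@dataclass
class IMURecording:
    """A uniformly sampled 6-axis inertial stream in SI units.

    Attributes
    ----------
    t : (n,) float array
        Sample times, seconds, strictly increasing on a uniform grid.
    accel : (n, 3) float array
        Specific force in the sensor frame, m/s^2.
    gyro : (n, 3) float array
        Angular rate in the sensor frame, rad/s.
    fs : float
        Sampling rate, Hz (100 in the lab set-up, 128 at home).
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    fs: float
    device_context: str = "home"   # "lab" | "home"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    def validate(self) -> None:
        n = self.n_samples
        if not (self.accel.shape == (n, 3) and self.gyro.shape == (n, 3)):
            raise ValueError("accel/gyro must be (n, 3) arrays matching the time base")
        if n < 2:
            raise ValueError("insufficient samples: an IMU recording needs at least 2")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        dt = np.diff(self.t)
        nominal = 1.0 / self.fs
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        worst = np.max(np.abs(dt - nominal))
        if worst > 0.01 * nominal:
            raise ValueError(
                f"non-uniform sampling: max spacing deviation {worst:.3e} s "
                f"exceeds 1% of the nominal {nominal:.4e} s interval"
            )


@dataclass(frozen=True)
class IntakeEvent:
    """One dopaminergic medication intake from the patient diary."""

    time: float          # seconds relative to recording start (may be negative)
    dose_label: str = ""


@dataclass
class LabTrial:
    """One supervised walking test with its task and medication-state labels."""

    recording: IMURecording
    task: str            # straight_normal | straight_fast | circular_left | circular_right
    med_state: str       # ON | OFF
    flags: set = field(default_factory=set)

    TASKS = ("straight_normal", "straight_fast", "circular_left", "circular_right")

    def __post_init__(self) -> None:
        if self.task not in self.TASKS:
            raise ValueError(f"unknown lab task {self.task!r}")
        if self.med_state not in ("ON", "OFF"):
            raise ValueError(f"med_state must be ON or OFF, got {self.med_state!r}")
        # Fast-pace walking in the OFF state is schema-legal but rare enough in
        # practice that it is flagged rather than analysed silently.
        if self.task == "straight_fast" and self.med_state == "OFF":
            self.flags.add("fast_pace_off_state")


# --------------------------------------------------------------------------- #
# unit normalization
# --------------------------------------------------------------------------- #

_ACCEL_SCALE = {"m/s^2": 1.0, "g": G}
_GYRO_SCALE = {"rad/s": 1.0, "deg/s": math.pi / 180.0}


def normalize_units(accel: np.ndarray, gyro: np.ndarray,
                    accel_units: str = "m/s^2", gyro_units: str = "rad/s"):
    """Convert raw channel values to SI (m/s^2, rad/s).

    Normalization is idempotent by construction: with SI unit declarations the
    conversion is the identity.
    """
    try:
        sa = _ACCEL_SCALE[accel_units]
        sg = _GYRO_SCALE[gyro_units]
    except KeyError as exc:
        raise ValueError(f"unknown unit declaration {exc.args[0]!r}") from exc
    return np.asarray(accel, float) * sa, np.asarray(gyro, float) * sg


# --------------------------------------------------------------------------- #
# readers / writers
# --------------------------------------------------------------------------- #

def read_imu(path: str | Path, accel_units: str = "m/s^2", gyro_units: str = "rad/s",
             fs_hint: float | None = None, device_context: str = "home",
             subject_id: str = "") -> IMURecording:
    """Read a ``time,ax,ay,az,gx,gy,gz`` CSV stream and normalize to SI units.

    The sampling rate is inferred from the timestamps and cross-checked
    against ``fs_hint`` (error if they disagree by more than 5%).  Gaps longer
    than 2 nominal sample intervals are reported as warnings.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed IMU file: {exc}") from exc
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df[IMU_COLUMNS]
    bad = df.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: malformed row at line {row + 2} (1-based, incl. header)")
    if len(df) < 2:
        raise ValueError(f"{path}: insufficient samples ({len(df)} row)")

    t = df["time"].to_numpy(float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.flatnonzero(dt <= 0)[0])
        raise ValueError(f"{path}: non-increasing timestamp at line {row + 3}")
    fs = 1.0 / float(np.median(dt))
    if fs_hint is not None and abs(fs - fs_hint) > 0.05 * fs_hint:
        raise ValueError(
            f"{path}: inferred sampling rate {fs:.2f} Hz disagrees with "
            f"declared {fs_hint:.2f} Hz by more than 5%"
        )
    n_gaps = int(np.sum(dt > 2.0 / fs))
    if n_gaps:
        warnings.warn(f"{path}: {n_gaps} gap(s) longer than 2 samples in the time base")

    accel, gyro = normalize_units(
        df[["ax", "ay", "az"]].to_numpy(float),
        df[["gx", "gy", "gz"]].to_numpy(float),
        accel_units, gyro_units,
    )
    rec = IMURecording(t=t, accel=accel, gyro=gyro, fs=fs,
                       device_context=device_context, subject_id=subject_id)
    rec.validate()
    return rec


def write_imu(rec: IMURecording, path: str | Path) -> None:
    """Write an SI-normalized recording; round-trips exactly through read_imu."""
    data = np.column_stack([rec.t, rec.accel, rec.gyro])
    np.savetxt(path, data, fmt="%.17g", delimiter=",",
               header=",".join(IMU_COLUMNS), comments="")


def read_diary(path: str | Path, t0=None, offset_s: float = 0.0) -> list[IntakeEvent]:
    """Read a ``timestamp,dose_label`` diary into intake events.

    Timestamps are either ISO-8601 wall-clock strings (``t0`` then defines
    second zero) or plain numbers already in seconds relative to recording
    start.  Events are sorted and deduplicated; intakes before ``t0`` are
    retained with negative times (with a warning).
    """
    df = pd.read_csv(path, dtype={"timestamp": str})
    if "timestamp" not in df.columns:
        raise ValueError(f"{path}: diary needs a 'timestamp' column")
    labels = df["dose_label"].astype(str) if "dose_label" in df.columns else [""] * len(df)
    if len(df) == 0:
        warnings.warn(f"{path}: empty diary")
        return []

    times = []
    for i, raw in enumerate(df["timestamp"]):
        try:
            times.append(float(raw))
            continue
        except (TypeError, ValueError):
            pass
        try:
            ts = pd.Timestamp(raw)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: unparseable timestamp {raw!r} at row {i + 2}") from exc
        if t0 is None:
            raise ValueError(f"{path}: wall-clock timestamps require a t0 reference")
        times.append((ts - pd.Timestamp(t0)).total_seconds())

    events = sorted({(t + offset_s, lbl) for t, lbl in zip(times, labels)})
    # dedup on time alone: identical times with different labels keep the first
    out, seen = [], set()
    for t, lbl in events:
        if t in seen:
            continue
        seen.add(t)
        out.append(IntakeEvent(time=t, dose_label=lbl))
    if any(e.time < 0 for e in out):
        warnings.warn(f"{path}: intake(s) before recording start retained with negative time")
    return out


def write_diary(events: list[IntakeEvent], path: str | Path) -> None:
    pd.DataFrame(
        {"timestamp": [e.time for e in events], "dose_label": [e.dose_label for e in events]}
    ).to_csv(path, index=False)


def read_clinical_scores(path: str | Path, require_state_difference: bool = False) -> pd.DataFrame:
    """Read UPDRS-III totals and item scores keyed by subject_id.

    With ``require_state_difference`` the cohort filter is applied: subjects
    whose ON/OFF total difference is below 2 points (the minimum clinically
    significant state contrast) are dropped.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "updrs3_on", "updrs3_off"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing clinical columns {sorted(missing)}")
    for col in ("updrs3_on", "updrs3_off"):
        if ((df[col] < 0) | (df[col] > 108)).any():
            raise ValueError(f"{path}: {col} outside the 0-108 UPDRS-III range")
    if require_state_difference:
        df = df[(df["updrs3_off"] - df["updrs3_on"]).abs() >= 2].reset_index(drop=True)
    return df


def write_report(result, json_path: str | Path, csv_path: str | Path | None = None) -> None:
    """Write a cohort analysis as nested JSON plus a flat comparison table.

    The flat table mirrors the published layout: one row per
    (lab task x home metric) cell with comparison p, r, correlation p and R^2.
    """
    with open(json_path, "w") as fh:
        json.dump(result.to_json_dict(), fh, indent=2)
    if csv_path is not None:
        result.flat_table().to_csv(csv_path, index=False)
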