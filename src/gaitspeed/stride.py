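"""Per-stride gait-speed estimation from a single foot-worn IMU.

The estimator is the canonical zero-velocity-update (ZUPT) strapdown
construction: detect foot-flat (motionless) periods, initialize orientation
from the gravity direction measured while the foot is flat, strapdown-
integrate the gyroscope through the swing, rotate specific force into the
navigation frame, remove gravity, integrate to velocity, force the velocity
back to zero at both bounding foot-flats by subtracting a linear drift ramp,
and integrate once more to displacement.  One gait cycle (stride) runs from a
foot-flat onset to the next foot-flat onset of the instrumented foot and
carries speed = ||displacement|| / cycle duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.transform import Rotation

from .constants import G
from .io import IMURecording, LabTrial

#: sanity bound on human gait speed, m/s; faster strides are flagged
MAX_PLAUSIBLE_SPEED = 4.0


@dataclass
class ZuptMask:
    """Per-sample stillness judgement with its derived still-interval list."""

    mask: np.ndarray                   # (n,) bool
    intervals: list[tuple[int, int]]   # half-open sample ranges [start, stop)
    fs: float


@dataclass
class StrideRecord:
    """One gait cycle: foot-flat onset to next foot-flat onset."""

    t_start: float
    t_end: float
    duration: float
    displacement: float      # 3-D norm, m
    speed: float             # m/s
    quality_flags: set = field(default_factory=set)


@dataclass
class TrialSpeedResult:
    """Steady-state summary of one lab trial (edge strides trimmed)."""

    strides: list[StrideRecord]
    retained: list[StrideRecord]
    mean_speed: float        # nan when no stride survives trimming
    n_trimmed: int
    flags: set = field(default_factory=set)


# --------------------------------------------------------------------------- #
# still detection
# --------------------------------------------------------------------------- #

def _close_small_gaps(mask: np.ndarray, max_gap: int) -> np.ndarray:
    """Fill false runs of length <= max_gap that are flanked by true samples."""
    if max_gap <= 0 or not mask.any():
        return mask
    out = mask.copy()
    padded = np.concatenate([[True], mask, [True]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == -1)   # first false sample of each gap
    stops = np.flatnonzero(diff == 1)     # one past last false sample
    for a, b in zip(starts, stops):
        if b - a <= max_gap and a > 0 and b < mask.size:
            out[a:b] = True
    return out


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def detect_still(rec: IMURecording, gyro_thresh: float = 0.8,
                 accel_band: float = 0.8, min_still: float = 0.08,
                 close_gap_samples: int = 2) -> ZuptMask:
    """Composite foot-flat detector.

    A sample is a still candidate when the gyro magnitude is below
    ``gyro_thresh`` (rad/s) and the accelerometer magnitude is within
    ``accel_band`` (m/s^2) of gravity.  Gaps of up to ``close_gap_samples``
    are closed morphologically, then only runs of at least ``min_still``
    seconds survive.  An empty mask is a legal result.
    """
    gmag = np.linalg.norm(rec.gyro, axis=1)
    amag = np.linalg.norm(rec.accel, axis=1)
    raw = (gmag < gyro_thresh) & (np.abs(amag - G) < accel_band)
    closed = _close_small_gaps(raw, close_gap_samples)
    min_samples = max(2, int(np.ceil(min_still * rec.fs)))
    intervals = [(a, b) for a, b in _true_runs(closed) if b - a >= min_samples]
    final = np.zeros_like(closed)
    for a, b in intervals:
        final[a:b] = True
    return ZuptMask(mask=final, intervals=intervals, fs=rec.fs)


# --------------------------------------------------------------------------- #
# strapdown integration with ZUPT
# --------------------------------------------------------------------------- #

def _gravity_alignment(accel_still: np.ndarray) -> Rotation:
    """Minimal rotation taking the measured gravity-up direction to world +z.

    Yaw is unobservable from gravity alone and irrelevant to the speed
    magnitude, so the minimal (no-twist) rotation is used.
    """
    u = accel_still.mean(axis=0)
    u = u / np.linalg.norm(u)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(u, z)
    s = np.linalg.norm(axis)
    c = float(np.dot(u, z))
    if s < 1e-12:
        if c > 0:
            return Rotation.identity()
        return Rotation.from_rotvec([np.pi, 0.0, 0.0])
    angle = np.arctan2(s, c)
    return Rotation.from_rotvec(axis / s * angle)


def _integrate_interval(t: np.ndarray, accel: np.ndarray, gyro: np.ndarray,
                        r0: Rotation):
    """Strapdown-integrate one inter-still segment.

    Returns the drift-corrected navigation-frame velocity time series and the
    final displacement vector.  The velocity is exactly zero at both segment
    boundaries by construction (ZUPT + linear dedrifting).
    """
    n = t.shape[0]
    dt = np.diff(t)
    # orientation propagation with midpoint body rates
    omega_mid = 0.5 * (gyro[:-1] + gyro[1:])
    deltas = Rotation.from_rotvec(omega_mid * dt[:, None])
    quats = np.empty((n, 4))
    r = r0
    quats[0] = r.as_quat()
    for k in range(n - 1):
        r = r * deltas[k]
        quats[k + 1] = r.as_quat()
    rots = Rotation.from_quat(quats)
    a_nav = rots.apply(accel)
    a_nav[:, 2] -= G
    v = cumulative_trapezoid(a_nav, t, axis=0, initial=0.0)
    # linear dedrift: remove the ramp that makes the terminal velocity nonzero
    ramp = (t - t[0]) / (t[-1] - t[0])
    v = v - ramp[:, None] * v[-1]
    disp = cumulative_trapezoid(v, t, axis=0, initial=0.0)[-1]
    return v, disp


def estimate_strides(rec: IMURecording, mask: ZuptMask,
                     max_stride_duration: float = 4.0,
                     max_stance: float = 1.5,
                     nominal_swing_fraction: float = 0.6,
                     return_velocities: bool = False):
    """Emit one StrideRecord per inter-still interval.

    Requires at least two still intervals; the inertial integration runs over
    the moving segment between the two bounding still intervals, and segments
    longer than ``max_stride_duration`` produce no stride.

    Gait-cycle timing is foot-flat onset to next foot-flat onset.  When the
    leading still interval is longer than ``max_stance`` (a rest gap) its
    onset is not a heel-strike of this walking sequence, so the cycle is
    timed toe-off to toe-off instead (flag ``bout_initial``);
    if the trailing still is also long the cycle duration is extrapolated
    from the swing time via ``nominal_swing_fraction`` (flag ``isolated``).
    """
    if len(mask.intervals) < 2:
        return ([], []) if return_velocities else []
    strides: list[StrideRecord] = []
    velocities = []
    t, accel, gyro = rec.t, rec.accel, rec.gyro
    max_stance_n = int(round(max_stance * rec.fs))
    for (a0, b0), (a1, b1) in zip(mask.intervals[:-1], mask.intervals[1:]):
        i0, i1 = b0 - 1, a1          # last still sample -> first still sample
        move_duration = t[i1] - t[i0]
        if move_duration > max_stride_duration:
            continue
        r0 = _gravity_alignment(accel[a0:b0])
        seg = slice(i0, i1 + 1)
        v, disp = _integrate_interval(t[seg], accel[seg], gyro[seg], r0)
        flags = set()
        leading_is_stance = (b0 - a0) <= max_stance_n
        t_end = t[a1]
        if leading_is_stance:
            t_start = t[a0]
            duration = t_end - t_start
        elif (b1 - a1) <= max_stance_n:
            flags.add("bout_initial")
            duration = t[b1 - 1] - t[b0 - 1]       # toe-off to toe-off
            t_start = t_end - duration
        else:
            flags.add("isolated")
            duration = move_duration / nominal_swing_fraction
            t_start = t_end - duration
        speed = float(np.linalg.norm(disp)) / duration
        if speed >= MAX_PLAUSIBLE_SPEED:
            flags.add("speed_out_of_range")
        strides.append(StrideRecord(
            t_start=float(t_start), t_end=float(t_end), duration=float(duration),
            displacement=float(np.linalg.norm(disp)), speed=speed,
            quality_flags=flags,
        ))
        if return_velocities:
            velocities.append(v)
    if return_velocities:
        return strides, velocities
    return strides


def strides_to_frame(strides: list[StrideRecord]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame({
        "t_start": [s.t_start for s in strides],
        "t_end": [s.t_end for s in strides],
        "duration": [s.duration for s in strides],
        "speed": [s.speed for s in strides],
        "flags": [";".join(sorted(s.quality_flags)) for s in strides],
    })


# --------------------------------------------------------------------------- #
# lab trials
# --------------------------------------------------------------------------- #

def steady_state_mean(speeds: np.ndarray, n_trim: int = 2):
    """Trim ``n_trim`` gait cycles at each end and average the rest.

    Returns ``(mean, n_trimmed, flags)``; the mean is nan (flagged) when no
    steady-state stride remains.
    """
    speeds = np.asarray(speeds, float)
    n = speeds.size
    n_trimmed = min(2 * n_trim, n)
    flags: set = set()
    if n < 2 * n_trim + 1:
        flags.add("insufficient_steady_state_strides")
        return float("nan"), n_trimmed, flags
    retained = speeds[n_trim:n - n_trim]
    return float(retained.mean()), n_trimmed, flags


def process_lab_trial(trial: LabTrial, gyro_thresh: float = 0.8,
                      accel_band: float = 0.8, min_still: float = 0.08,
                      max_stride_duration: float = 4.0,
                      n_trim: int = 2) -> TrialSpeedResult:
    """Estimate strides for one supervised test and report its steady-state mean.

    The first and last ``n_trim`` gait cycles are excluded so gait-initiation
    and termination do not bias the trial mean.
    """
    trial.recording.validate()
    mask = detect_still(trial.recording, gyro_thresh=gyro_thresh,
                        accel_band=accel_band, min_still=min_still)
    strides = estimate_strides(trial.recording, mask,
                               max_stride_duration=max_stride_duration)
    speeds = np.array([s.speed for s in strides])
    mean, n_trimmed, flags = steady_state_mean(speeds, n_trim=n_trim)
    retained = strides[n_trim:len(strides) - n_trim] if len(strides) >= 2 * n_trim + 1 else []
    flags |= trial.flags
    return TrialSpeedResult(strides=strides, retained=retained, mean_speed=mean,
                            n_trimmed=n_trimmed, flags=flags)
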