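"""Synthetic data with analytic ground truth.

Three layers are generated, each with complete ground truth and full
determinism under a fixed seed:

* raw foot-IMU stride signals from a closed-form swing trajectory (so the
  true displacement and speed of every stride are known exactly);
* simulated 12-hour home days: a medication-intake schedule, a bout process
  whose rate/duration/speed depend on the medication state, and a stride
  truth table (optionally rendered to a raw signal);
* whole cohorts with a shared latent walking capacity per subject that links
  supervised lab-test speeds to the tails of the home speed distribution.

The swing trajectory is a minimum-jerk horizontal profile with a smooth
vertical clearance bump and a pitch excursion, all polynomial in normalized
swing time, so accelerations and angular rates are exact derivatives and the
velocity profile is exactly zero at both foot-flats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bouts import build_state_timeline
from .constants import G
from .io import IMURecording, IntakeEvent
from .stride import StrideRecord


# --------------------------------------------------------------------------- #
# stride-level kinematics
# --------------------------------------------------------------------------- #

@dataclass
class NoiseModel:
    """Additive sensor noise, consumer-grade MEMS magnitudes."""

    accel_sigma: float = 0.05   # m/s^2, white
    gyro_sigma: float = 0.01    # rad/s, white
    gyro_bias: float = 0.005    # rad/s, constant per recording, random direction


@dataclass
class StrideKinematicsSpec:
    """One gait cycle: stride length, cycle duration and signal parameters."""

    stride_length: float               # m
    duration: float                    # s, full gait cycle (stance + swing)
    swing_fraction: float = 0.6
    fs: float = 128.0
    clearance: float = 0.05            # m, peak foot lift during swing
    pitch_max: float = 0.35            # rad, peak sagittal foot pitch
    turn_angle: float = 0.0            # rad, yaw change over the swing (curved walking)
    noise: NoiseModel = field(default_factory=NoiseModel)


# polynomials in normalized swing time s in [0, 1], low-to-high coefficients
_P_X = np.polynomial.Polynomial([0, 0, 0, 10, -15, 6])          # minimum jerk
_P_Z = np.polynomial.Polynomial([0, 0, 0, 1, -3, 3, -1]) * 64   # s^3 (1-s)^3
_P_TH = (np.polynomial.Polynomial([0, 0, 1, -2, 1])             # s^2 (1-s)^2
         * np.polynomial.Polynomial([1, -2]))                   # * (1-2s)
_TH_NORM = float(np.max(np.abs(_P_TH(np.linspace(0, 1, 4001)))))


def _swing_signals(spec: StrideKinematicsSpec, n_swing: int):
    """Ideal body-frame gyro and specific force over one swing of n samples.

    The sample at index 0 is the last foot-flat instant (s=0); index
    ``n_swing`` would be the next foot-flat (owned by the following stance).
    """
    tau = n_swing / spec.fs
    s = np.arange(n_swing) / n_swing
    L, h = spec.stride_length, spec.clearance
    ax = L * _P_X.deriv(2)(s) / tau**2
    az = h * _P_Z.deriv(2)(s) / tau**2
    theta = spec.pitch_max / _TH_NORM * _P_TH(s)
    theta_dot = spec.pitch_max / _TH_NORM * _P_TH.deriv()(s) / tau
    # yaw follows a minimum-jerk ramp (zero rate at both foot-flats); the foot
    # translates along the same straight chord, so the truth speed is unchanged
    psi = spec.turn_angle * _P_X(s)
    psi_dot = spec.turn_angle * _P_X.deriv()(s) / tau

    c, sn = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(psi), np.sin(psi)
    w_x, w_z = ax, az + G                    # a_world - g_world
    # f_body = Ry(theta)^T Rz(psi)^T (w_x, 0, w_z)
    f = np.zeros((n_swing, 3))
    f[:, 0] = c * (cp * w_x) - sn * w_z
    f[:, 1] = -sp * w_x
    f[:, 2] = sn * (cp * w_x) + c * w_z
    # body rates for R = Rz(psi) Ry(theta)
    gyro = np.zeros((n_swing, 3))
    gyro[:, 0] = -psi_dot * sn
    gyro[:, 1] = theta_dot
    gyro[:, 2] = psi_dot * c
    return gyro, f


def _still_signals(n: int):
    f = np.zeros((n, 3))
    f[:, 2] = G
    return np.zeros((n, 3)), f


# --------------------------------------------------------------------------- #
# walks
# --------------------------------------------------------------------------- #

@dataclass
class WalkTruth:
    strides: pd.DataFrame                   # t_start, t_end, duration, speed, bout_id
    still_intervals: list[tuple[float, float]]  # true foot-flat/rest periods, s


def synth_walk(bouts: list, rest_gaps=10.0, noise: NoiseModel | None = None,
               seed=None, rng: np.random.Generator | None = None,
               tail_s: float | None = None, subject_id: str = "",
               device_context: str = "home") -> tuple[IMURecording, WalkTruth]:
    """Concatenate strides (grouped into bouts) into one continuous recording.

    ``bouts`` is a list of bouts, each a list of StrideKinematicsSpec (a flat
    list of specs is treated as a single bout).  Rest segments of
    ``rest_gaps`` seconds (scalar, or one value per inter-bout gap) separate
    bouts; a trailing still segment closes the final stride.  Each stride is
    rendered as [stance, swing] so that foot-flat onsets delimit gait cycles
    exactly; the truth table stores per-stride start/end/duration/speed on
    the realized sample grid.
    """
    if bouts and isinstance(bouts[0], StrideKinematicsSpec):
        bouts = [bouts]
    if not bouts or not any(bouts):
        raise ValueError("synth_walk needs at least one stride")
    rng = rng if rng is not None else np.random.default_rng(seed)
    specs0 = bouts[0][0]
    fs = specs0.fs
    noise = noise if noise is not None else specs0.noise
    n_gaps = len(bouts) - 1
    gaps = np.broadcast_to(np.asarray(rest_gaps, float), (n_gaps,)) if n_gaps else []

    gyro_parts, accel_parts = [], []
    truth_rows, still_ivs = [], []
    cursor = 0  # samples

    def emit_still(n):
        nonlocal cursor
        g, f = _still_signals(n)
        gyro_parts.append(g)
        accel_parts.append(f)
        still_ivs.append((cursor / fs, (cursor + n) / fs))
        cursor += n

    for b_idx, bout in enumerate(bouts):
        for spec in bout:
            if spec.fs != fs:
                raise ValueError("all strides in a walk must share one sampling rate")
            n_total = int(round(spec.duration * spec.fs))
            if n_total < 20:
                raise ValueError("stride too short: fewer than 20 samples")
            n_swing = int(round(spec.swing_fraction * spec.duration * spec.fs))
            n_stance = n_total - n_swing
            t_start = cursor / fs
            emit_still(n_stance)
            g, f = _swing_signals(spec, n_swing)
            gyro_parts.append(g)
            accel_parts.append(f)
            cursor += n_swing
            duration = n_total / fs
            truth_rows.append({
                "t_start": t_start, "t_end": t_start + duration,
                "duration": duration, "speed": spec.stride_length / duration,
                "stride_length": spec.stride_length, "bout_id": b_idx,
            })
        if b_idx < len(bouts) - 1:
            emit_still(int(round(gaps[b_idx] * fs)))
    # trailing still closes the last gait cycle
    last = bouts[-1][-1]
    tail = tail_s if tail_s is not None else (1 - last.swing_fraction) * last.duration
    emit_still(max(int(round(tail * fs)), int(round(0.1 * fs))))

    gyro = np.concatenate(gyro_parts)
    accel = np.concatenate(accel_parts)
    if noise.accel_sigma > 0:
        accel = accel + rng.normal(0.0, noise.accel_sigma, accel.shape)
    if noise.gyro_sigma > 0:
        gyro = gyro + rng.normal(0.0, noise.gyro_sigma, gyro.shape)
    if noise.gyro_bias > 0:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        gyro = gyro + noise.gyro_bias * direction

    t = np.arange(cursor) / fs
    rec = IMURecording(t=t, accel=accel, gyro=gyro, fs=fs,
                       device_context=device_context, subject_id=subject_id)
    truth = WalkTruth(strides=pd.DataFrame(truth_rows), still_intervals=still_ivs)
    return rec, truth


def synth_stride_signal(spec: StrideKinematicsSpec, seed=None,
                        rng: np.random.Generator | None = None
                        ) -> tuple[IMURecording, StrideRecord]:
    """One gait cycle as a standalone recording, with its exact truth record."""
    if spec.duration * spec.fs < 20:
        raise ValueError("duration * fs must be at least 20 samples")
    rec, truth = synth_walk([[spec]], rng=rng, seed=seed)
    row = truth.strides.iloc[0]
    return rec, StrideRecord(t_start=row.t_start, t_end=row.t_end,
                             duration=row.duration,
                             displacement=spec.stride_length, speed=row.speed)


def reintegrate_displacement(rec: IMURecording, truth: WalkTruth) -> np.ndarray:
    """Analytic self-check: double-integrate the noiseless emitted signals.

    Pitch is recovered by direct trapezoidal integration of the emitted pitch
    rate (the generator rotates about a single axis), specific force is
    rotated back to the world frame, gravity removed, and the result
    double-integrated over each stride's swing window -- no zero-velocity
    updates and no drift correction, so this path is independent of the
    estimator.  Simpson quadrature keeps the check's own numerical error far
    below the tolerance it verifies.  Returns per-stride displacement norms.
    """
    from scipy.integrate import cumulative_simpson

    swing_windows = []
    stills = truth.still_intervals
    for (a0, b0), (a1, b1) in zip(stills[:-1], stills[1:]):
        swing_windows.append((b0, a1))

    out = []
    for t0, t1 in swing_windows:
        sel = (rec.t >= t0 - 0.5 / rec.fs) & (rec.t <= t1 + 0.5 / rec.fs)
        t = rec.t[sel]
        gy = rec.gyro[sel, 1]
        f = rec.accel[sel]
        theta = cumulative_simpson(gy, x=t, initial=0.0)
        c, s = np.cos(theta), np.sin(theta)
        a_w = np.zeros_like(f)
        a_w[:, 0] = c * f[:, 0] + s * f[:, 2]
        a_w[:, 1] = f[:, 1]
        a_w[:, 2] = -s * f[:, 0] + c * f[:, 2] - G
        v = cumulative_simpson(a_w, x=t, axis=0, initial=0.0)
        d = cumulative_simpson(v, x=t, axis=0, initial=0.0)[-1]
        out.append(float(np.linalg.norm(d)))
    return np.array(out)


# --------------------------------------------------------------------------- #
# simulated days
# --------------------------------------------------------------------------- #

@dataclass
class DayScenario:
    """A 12-h home recording: intake schedule, bout process, speed model.

    Stride speeds follow the latent-capacity model: the subject's capacity
    ``c`` is drawn once, ON strides are N(c*k_on, sigma_w), not-ON strides
    N(c*k_off, sigma_w) with k_off < k_on, all truncated positive.
    """

    duration_s: float = 12 * 3600.0
    intake_times: tuple = (1800.0, 16200.0, 30600.0)   # ~9:30, 13:30, 17:30
    bout_rate_per_h: dict = field(default_factory=lambda: {
        "ON": 4.0, "not_ON": 3.0, "unlabeled": 3.5})
    bout_duration_lognorm: dict = field(default_factory=lambda: {
        "ON": (math.log(25.0), 0.7), "not_ON": (math.log(20.0), 0.7),
        "unlabeled": (math.log(22.0), 0.7)})
    capacity_mean: float = 1.15        # m/s
    capacity_sd: float = 0.15
    k_on: float = 0.75
    k_off: float = 0.65
    sigma_w: float = 0.15              # within-subject stride-speed sd, m/s
    stride_duration_mean: float = 1.1  # s
    stride_duration_sd: float = 0.08
    seed: int | None = None


@dataclass
class DayData:
    strides: pd.DataFrame              # t_start, t_end, duration, speed, true_state, bout_id
    diary: list[IntakeEvent]
    capacity: float
    recording: IMURecording | None = None
    recording_truth: WalkTruth | None = None


def _default_speed_sampler(scenario: DayScenario):
    k = {"ON": scenario.k_on, "not_ON": scenario.k_off,
         "unlabeled": 0.5 * (scenario.k_on + scenario.k_off)}

    def sampler(rng, state, n, c):
        v = rng.normal(c * k[state], scenario.sigma_w, n)
        return np.clip(v, 0.05, None)

    return sampler


def synth_day(scenario: DayScenario, seed=None, rng: np.random.Generator | None = None,
              capacity: float | None = None, speed_sampler=None,
              signal: bool = False, noise: NoiseModel | None = None) -> DayData:
    """Simulate one patient day: diary, bout process, stride truth table.

    Bout onsets follow a Poisson process whose rate depends on the medication
    state at the onset (from the intake-window timeline); bout durations are
    log-normal per state and stride speeds come from ``speed_sampler`` (the
    scenario's latent-capacity model by default).  With ``signal=True`` the
    day is also rendered to a raw IMU stream (intended for shortened days:
    a full 12-h signal is ~33 M samples).
    """
    rng = rng if rng is not None else np.random.default_rng(
        seed if seed is not None else scenario.seed)
    timeline = build_state_timeline(scenario.intake_times)
    c = capacity if capacity is not None else float(
        np.clip(rng.normal(scenario.capacity_mean, scenario.capacity_sd), 0.3, None))
    sampler = speed_sampler if speed_sampler is not None else _default_speed_sampler(scenario)

    rows = []
    t = 0.0
    bout_id = 0
    while True:
        state_here = timeline.label(t)
        rate = scenario.bout_rate_per_h[state_here] / 3600.0
        t = t + rng.exponential(1.0 / rate)
        if t >= scenario.duration_s:
            break
        state = timeline.label(t)
        mu, sig = scenario.bout_duration_lognorm[state]
        bout_dur = float(rng.lognormal(mu, sig))
        if t + bout_dur > scenario.duration_s:
            break
        # tile strides through the bout
        n_max = int(bout_dur / (scenario.stride_duration_mean - 3 * scenario.stride_duration_sd)) + 2
        durs = np.clip(rng.normal(scenario.stride_duration_mean,
                                  scenario.stride_duration_sd, n_max), 0.7, 1.6)
        ends = np.cumsum(durs)
        n = int(np.searchsorted(ends, bout_dur))
        if n < 1:
            continue
        speeds = sampler(rng, state, n, c)
        starts = t + np.concatenate([[0.0], ends[:n - 1]])
        for ts, d, v in zip(starts, durs[:n], speeds):
            rows.append({"t_start": ts, "t_end": ts + d, "duration": d,
                         "speed": v, "true_state": state, "bout_id": bout_id})
        t += bout_dur
        bout_id += 1

    strides = pd.DataFrame(rows, columns=["t_start", "t_end", "duration",
                                          "speed", "true_state", "bout_id"])
    diary = [IntakeEvent(time=ti, dose_label=f"dose_{i + 1}")
             for i, ti in enumerate(scenario.intake_times)]
    day = DayData(strides=strides, diary=diary, capacity=c)

    if signal and len(strides):
        noise = noise if noise is not None else NoiseModel()
        bouts, gaps = [], []
        for bid, grp in strides.groupby("bout_id"):
            specs = [StrideKinematicsSpec(stride_length=r.speed * r.duration,
                                          duration=r.duration, noise=noise)
                     for r in grp.itertuples()]
            bouts.append(specs)
        bout_starts = strides.groupby("bout_id")["t_start"].first().to_numpy()
        bout_ends = strides.groupby("bout_id")["t_end"].last().to_numpy()
        gaps = list(np.maximum(bout_starts[1:] - bout_ends[:-1], 2.0))
        day.recording, day.recording_truth = synth_walk(
            bouts, rest_gaps=gaps if gaps else 10.0, noise=noise, rng=rng)
    return day


# --------------------------------------------------------------------------- #
# cohorts
# --------------------------------------------------------------------------- #

@dataclass
class CohortScenario:
    """A full study cohort with a shared latent capacity per subject.

    Lab task targets are deterministic functions of capacity ``c`` (normal
    pace = c, fast = attain*c, circular = 0.7*c, OFF scaled down per task).
    Home bout mean speeds come from a per-bout intensity model that encodes
    state-dependent tail linkage:

    * ON: intensity beta ~ U(beta_range); attainable speed attain*c*beta is
      floored by a capacity-independent "context floor" (unhurried indoor
      walking), so high percentiles track capacity tightly while low
      percentiles mostly reflect context;
    * not-ON: capacity is scaled by k_off, no context floor binds (slowness
      genuinely reflects the impairment, which scales with the subject), and
      bout-level noise grows with intensity, so *low* percentiles track the
      subject best.
    """

    n_subjects: int = 27
    capacity_mean: float = 1.15
    capacity_sd: float = 0.18
    capacity_min: float = 0.6
    attain: float = 1.25               # fast-pace / burst multiplier on capacity
    k_off: float = 0.92                # not-ON capacity scale at home
    beta_range: tuple = (0.35, 1.0)
    context_floor: tuple | None = (0.62, 0.10)   # (mean, sd) m/s; None disables
    sigma_bout_on: float = 0.05
    sigma_bout_off: tuple = (0.02, 0.35)         # bout-level sd at (low, high) beta
    sigma_stride: float = 0.08
    sigma_task: float = 0.04
    lab_off_ratio: dict = field(default_factory=lambda: {
        "straight_normal": 0.96, "circular": 0.84})
    n_lab_strides: int = 18
    sigma_lab_stride: float = 0.03     # stride-to-stride sd within a lab trial
    speed_model: str = "tail_linked"   # tail_linked | simple (DayScenario model)
    day: DayScenario = field(default_factory=DayScenario)
    seed: int | None = None


@dataclass
class CohortData:
    lab_strides: pd.DataFrame          # subject_id, task, med_state, stride_idx, speed
    home_strides: pd.DataFrame         # subject_id + day truth columns
    diaries: dict                      # subject_id -> list[IntakeEvent]
    clinical: pd.DataFrame
    truth: pd.DataFrame                # subject_id, capacity
    scenario: CohortScenario


def _cohort_speed_sampler(sc: CohortScenario, rng: np.random.Generator):
    b0, b1 = sc.beta_range
    s_lo, s_hi = sc.sigma_bout_off

    def sampler(rng_, state, n, c):
        beta = rng_.uniform(b0, b1)
        if state == "not_ON":
            sig = s_lo + (s_hi - s_lo) * (beta - b0) / (b1 - b0)
            mu = sc.attain * sc.k_off * c * beta + rng_.normal(0.0, sig)
        else:
            k = 1.0 if state == "ON" else 0.5 * (1.0 + sc.k_off)
            mu = sc.attain * k * c * beta
            if sc.context_floor is not None:
                mu = max(mu, rng_.normal(*sc.context_floor))
            mu += rng_.normal(0.0, sc.sigma_bout_on)
        return np.clip(rng_.normal(mu, sc.sigma_stride, n), 0.05, None)

    return sampler


def _lab_stride_speeds(rng, target: float, n: int, sigma: float = 0.03) -> np.ndarray:
    """A lab trial's stride speeds: ramp-up, steady state, ramp-down."""
    steady = rng.normal(target, sigma, max(n - 4, 0))
    return np.concatenate([[0.5 * target, 0.8 * target], steady,
                           [0.8 * target, 0.5 * target]])


def synth_cohort(scenario: CohortScenario | None = None, seed=None,
                 rng: np.random.Generator | None = None) -> CohortData:
    """Generate lab trials, home days, diaries, clinical scores and truth."""
    sc = scenario if scenario is not None else CohortScenario()
    rng = rng if rng is not None else np.random.default_rng(
        seed if seed is not None else sc.seed)

    lab_rows, home_frames, clin_rows, truth_rows = [], [], [], {}
    diaries = {}
    sampler = (_cohort_speed_sampler(sc, rng) if sc.speed_model == "tail_linked"
               else _default_speed_sampler(sc.day))
    for i in range(sc.n_subjects):
        sid = f"S{i + 1:02d}"
        c = float(np.clip(rng.normal(sc.capacity_mean, sc.capacity_sd),
                          sc.capacity_min, None))
        truth_rows[sid] = c

        # fast pace is an ON-only task (rarely feasible during OFF)
        targets = {
            ("straight_normal", "ON"): c,
            ("straight_fast", "ON"): sc.attain * c,
            ("circular_left", "ON"): 0.7 * c,
            ("circular_right", "ON"): 0.7 * c,
            ("straight_normal", "OFF"): sc.lab_off_ratio["straight_normal"] * c,
            ("circular_left", "OFF"): sc.lab_off_ratio["circular"] * 0.7 * c,
            ("circular_right", "OFF"): sc.lab_off_ratio["circular"] * 0.7 * c,
        }
        for (task, state), v in targets.items():
            v_trial = v + rng.normal(0.0, sc.sigma_task)
            speeds = _lab_stride_speeds(rng, v_trial, sc.n_lab_strides,
                                        sigma=sc.sigma_lab_stride)
            for j, sp in enumerate(speeds):
                lab_rows.append({"subject_id": sid, "task": task,
                                 "med_state": state, "stride_idx": j,
                                 "speed": float(max(sp, 0.05))})

        day = synth_day(sc.day, rng=rng, capacity=c, speed_sampler=sampler)
        df = day.strides.copy()
        df.insert(0, "subject_id", sid)
        home_frames.append(df)
        diaries[sid] = day.diary

        u_off = int(np.clip(round(70 - 35 * c + rng.normal(0, 6)), 5, 100))
        delta = int(2 + round(abs(rng.normal(4, 2))))
        u_on = max(u_off - delta, 0)
        i30_off = int(np.clip(round(3.2 - 1.8 * c + rng.normal(0, 0.5)), 0, 4))
        i30_on = int(np.clip(i30_off - rng.integers(0, 2), 0, 4))
        clin_rows.append({"subject_id": sid, "updrs3_on": u_on, "updrs3_off": u_off,
                          "item30_on": i30_on, "item30_off": i30_off})

    return CohortData(
        lab_strides=pd.DataFrame(lab_rows),
        home_strides=pd.concat(home_frames, ignore_index=True),
        diaries=diaries,
        clinical=pd.DataFrame(clin_rows),
        truth=pd.DataFrame({"subject_id": list(truth_rows), "capacity": list(truth_rows.values())}),
        scenario=sc,
    )
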