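# Methods

This note documents the models, parameter choices and numerics behind the
package, and what its synthetic-data tests do and do not demonstrate about
real recordings.

## Stride-speed estimation (ZUPT strapdown)

The estimator assumes a single 6-axis IMU rigidly attached to one foot,
with channels normalized to SI units (m/s², rad/s) and a uniform sample
grid at the device rate (no resampling: all algorithms are parameterized by
`fs`, so 100 Hz lab and 128 Hz home recordings go through identical code).

**Still detection.** A sample is foot-flat when the gyro magnitude is below
`gyro_thresh` (default 0.8 rad/s) *and* the accelerometer magnitude is
within `accel_band` (0.8 m/s²) of g = 9.81 m/s². Gaps of ≤ 2 samples are
closed morphologically and only runs of at least `min_still` (0.08 s)
survive. All three thresholds are config keys; the defaults are the
conventional values for pedestrian dead reckoning and are deliberately
loose — the ZUPT correction, not the detector, carries the accuracy.

**Integration.** For each inter-still segment: initialize orientation by
the minimal rotation aligning the mean still-period accelerometer vector
with world +z (yaw is unobservable from gravity and irrelevant to a speed
magnitude, so the device can be mounted in any orientation — verified by a
random-rotation invariance test); propagate orientation through the swing
with midpoint-rate quaternion updates; rotate specific force to the
navigation frame; subtract gravity; integrate with the trapezoid rule. The
terminal velocity of the segment is the accumulated drift; subtracting a
linear ramp makes velocity exactly zero at both bounding foot-flats (this
is the "linear dedrifting" variant; orientation-error feedback schemes
exist, but the linear ramp is the simplest member of the family and fully
determined by the ZUPT constraint). One more integration gives the 3-D
displacement, and `speed = ‖Δx‖ / T`.

**Gait-cycle timing.** A stride runs from a foot-flat onset (heel strike)
to the next. When the leading still interval is longer than `max_stance`
(1.5 s) — a rest gap — its onset is not a heel strike of this walking
sequence, so the cycle is timed toe-off to toe-off instead (flagged
`bout_initial`); if both bounding stills are long the duration is
extrapolated from the swing time with a nominal swing fraction of 0.6
(flagged `isolated`). Moving segments longer than `max_stride_duration`
(4 s) emit no stride; speeds ≥ 4 m/s are flagged implausible.

**Lab trials.** The first and last two gait cycles of each supervised test
are discarded (gait initiation/termination); trials with fewer than five
detected cycles have an undefined steady-state mean and are flagged. The
two circular-walking directions are averaged into one circular task. The
fast-pace task is treated as ON-only (it is rarely feasible in OFF and is
flagged when it appears).

## Bouts and medication states

Bouts are maximal stride runs with inter-stride gaps ≤ `max_gap_s` (3 s, the
conventional free-living break threshold; configurable). Duration classes
use closed/open edges matching the printed intervals: `<15` excluded,
`[15, 30]` short, `(30, 60]` medium, `(60, ∞)` long — the 30 s tie goes to
short because medium is open on the left. The 0.2 m/s stride floor applies
to home *summaries* only (bout membership is decided first; lab trials use
the trim rule instead), and the boundary value 0.2 is kept ("less than").

State windows per intake: ON `[t+60 min, t+180 min)`, not-ON
`[t−30 min, t+30 min)`, half-open so a bout midpoint exactly on a left edge
belongs to the window. When windows from different doses collide (inter-dose
interval < 210 min) not-ON wins by default — proximity to an intake means
the drug effect is not yet established — with `on_wins` and `drop` as
config alternatives. Bouts and strides are labeled by the state containing
their midpoint (deterministic, order-free); both bout-level and
stride-level labels are emitted because summaries use strides for the
percentile view and bouts for the bout-class view. Time outside any window
stays unlabeled; late end-of-dose wearing-off periods are therefore *not*
treated as not-ON. Diary-to-sensor clock offset is configurable
(`diary_offset_s`, default 0) since the synchronization between the two is
otherwise undefined.

## Summaries and statistics

Percentiles use linear interpolation on the sorted sample (the common
default; fixed so results are reproducible). The per-subject summary holds
p25/p50/p75/p90/max of all retained stride speeds and, per bout class, the
p25/p50/max of per-bout mean speeds (bout means recomputed over retained
strides). Empty cells are NaN and flagged, never silently dropped.

Paired contrasts apply Shapiro–Wilk at α = 0.05 to the paired *differences*
(the paired t-test's assumption concerns the differences, not the margins)
and choose paired *t* or Wilcoxon signed-rank (exact where size and ties
permit; all-zero differences are flagged degenerate, n < 3 is flagged).
Correlations apply Shapiro–Wilk to each margin and choose Pearson only if
both pass; bands on |r|: < 0.5 low, 0.5–0.7 moderate, > 0.7 high (magnitude,
because clinical-score correlations are negative). R² comes from a
straight-line fit of home on lab after a natural-log transform of whichever
variable(s) failed normality (speeds are positive; a non-positive value
blocks the transform and is flagged). When Pearson is used untransformed,
R² = r² to 10⁻¹⁰ by construction. No multiple-testing correction is applied
by default; Benjamini–Hochberg is available behind `mt_correction`.

The comparison column of the grid tests lab value vs home value for the
same subjects — the natural reading of a per-cell "comparison p" — and is
documented here as an interpretation.

## Synthetic data

**Stride signals.** The swing trajectory is analytic: minimum-jerk
horizontal profile (`x(s) = L(10s³−15s⁴+6s⁵)`), a degree-6 polynomial
clearance bump (peak 5 cm), a polynomial sagittal pitch excursion (peak
0.35 rad) and, for curved walking, a minimum-jerk yaw ramp — all with zero
velocity *and* zero acceleration/rate at the foot-flats, so signals join
stance segments smoothly and the displacement integral equals the stride
length exactly. Each stride is rendered as [stance, swing] so foot-flat
onsets delimit cycles exactly on the sample grid; truth tables carry the
realized (grid-quantized) durations. Sensor noise is white Gaussian
(accelerometer σ = 0.05 m/s², gyro σ = 0.01 rad/s) plus a constant
random-direction gyro bias of 0.005 rad/s — consumer-MEMS magnitudes. A
Simpson-quadrature re-integration of the noiseless signals, independent of
the estimator, reproduces stride length to < 10⁻³ m.

**Days.** A simulated day is 12 h with three intakes at 0.5 h, 4.5 h and
8.5 h (a typical three-dose schedule over a 9:00–21:00 wearing window).
Bout onsets follow a Poisson process whose rate depends on the current
state (4/h ON, 3/h not-ON, 3.5/h unlabeled — roughly 45 bouts/day); bout
durations are log-normal per state (medians 25/20/22 s, σ = 0.7, spanning
all three classes); stride durations are ~N(1.1 s, 0.08 s). The default
speed model is the latent-capacity form: capacity c ~ N(1.15, 0.15) m/s,
stride speed ~ N(c·k_state, σ_w) with k_on = 0.75, k_off = 0.65,
σ_w = 0.15 — these defaults put the home ON median near 0.85 m/s and the
ON/not-ON contrast near 0.1 m/s, the plausible scale for a mildly
fluctuating cohort.

**Cohorts.** Each of 27 subjects draws a capacity c ~ N(1.15, 0.18) m/s.
Lab targets are deterministic in c (normal = c, fast = 1.25c,
circular = 0.7c; OFF scaled by 0.96/0.84 for normal/circular, matching a
mild state effect), rendered as 18-stride trials with slow ramp-in/out
cycles so the trim rule matters. Home bout means come from an intensity
model that encodes *state-dependent tail linkage*:

- ON: intensity β ~ U(0.35, 1), attainable speed 1.25·c·β, floored by a
  capacity-independent "context floor" ~N(0.62, 0.10) m/s (unhurried
  indoor walking). High percentiles therefore track capacity tightly while
  low percentiles mostly reflect context.
- not-ON: capacity scaled by 0.92, no floor binds (slowness genuinely
  reflects the impairment, which scales with the subject), and bout-level
  noise grows linearly with β from 0.02 to 0.35 m/s — so the *low*
  percentiles are the best-linked home metric.

This construction reproduces, by design, the qualitative signature the
analysis is meant to detect: during ON, the fast-pace lab test correlates
more strongly with the home maximum than with the 25th percentile (and the
correlation rises monotonically across percentiles, on average); during
OFF/not-ON, lab tasks correlate best with the 25th percentile. The test
suite asserts exactly these orderings over 200 seeded cohorts; single
cohorts at n = 27 are noisy and need not show every ordering.

**What the generator does not emulate.** Real foot-IMU data contain
scuffing and shuffling strides, stairs and slopes, tremor and dyskinesia
oscillations, magnetometer-free heading drift during turns longer than one
stride, sensor re-mounting, and diary errors; none are modeled. The
generator's state contrast is distribution-wide (multiplicative in
capacity), whereas fluctuating patients may show tail-dominant contrasts;
consequently which percentile separates states most significantly in the
synthetic cohort need not match any particular clinical cohort. Passing
tests demonstrate the pipeline's correctness and calibration under known
ground truth, not clinical validity.

## Numerical choices and problem sizes

- g = 9.81 m/s² everywhere (generator, unit conversion, estimator).
- Orientation: scipy `Rotation`, midpoint body rates per step.
- Quadrature: trapezoid in the estimator (the ZUPT ramp removes its
  leading error term); Simpson in the generator self-check.
- Percentile rule: NumPy linear interpolation.
- Exact Wilcoxon where scipy's exact path applies (no ties/zeros,
  moderate n); cross-checked against full 2ⁿ sign enumeration in tests.
- Experiment sizes: 520 strides for speed-recovery error; 1000 replicates
  for type-I calibration; 500 replicate cohorts for the null state-effect
  check; 200 seeded cohorts (stride-table mode) for the tail-linkage
  orderings. These sizes give stable means (SEs well below the asserted
  margins) while keeping the whole suite in a few minutes on one CPU;
  signal-level end-to-end tests use shortened days because a full 12-h
  recording at 128 Hz is ~33 M samples.

## Known limitations

- The estimator assumes the ZUPT constraint holds at every detected still;
  very slow shuffling (< 0.2 m/s) blurs the still/swing boundary — such
  strides are exactly the ones the 0.2 m/s floor removes downstream.
- Bout-initial strides use surrogate timing (toe-off to toe-off) and very
  isolated strides use an assumed swing fraction; both are flagged.
- The state timeline ignores dose size and pharmacokinetics; windows are
  fixed offsets from intake times, as defined.
- `read_imu` expects the documented CSV dialect; vendor binary formats are
  out of scope by design (convert upstream).
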