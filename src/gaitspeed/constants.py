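"""Physical constants and shared labels."""

#: Gravitational acceleration used throughout (generator and estimator), m/s^2.
G = 9.81

#: Walking-bout duration classes, seconds.
#: excluded_short: d < 15;  short: 15 <= d <= 30;  medium: 30 < d <= 60;  long: d > 60.
BOUT_SHORT_MIN_S = 15.0
BOUT_SHORT_MAX_S = 30.0
BOUT_MEDIUM_MAX_S = 60.0

#: Stride speeds below this are treated as static periods in home summaries, m/s.
MIN_STRIDE_SPEED = 0.2

#: Medication-state windows relative to an intake, seconds.
ON_WINDOW_S = (3600.0, 10800.0)       # 60-180 min after intake
NOTON_WINDOW_S = (-1800.0, 1800.0)    # 30 min before to 30 min after intake

PERCENTILE_KEYS = ("p25", "p50", "p75", "p90", "max")
PERCENTILE_Q = {"p25": 25.0, "p50": 50.0, "p75": 75.0, "p90": 90.0, "max": 100.0}
WB_CLASSES = ("short", "medium", "long")
WB_STAT_KEYS = ("p25", "p50", "max")
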