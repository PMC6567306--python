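"""Build a reference week and score each day's similarity against it.

The reference window is chosen automatically as the 7 consecutive days with
the lowest dispersion of hourly counts; each day then gets a similarity
index in [-1, 1] (1 = identical routine to the reference).
"""

from pheromap import analyze_counts, hourly_counts, preprocess
from pheromap.simulate import (
    default_profile,
    generate_routine_log,
    scenario_mapping,
    standard_scenario,
)

profile = default_profile()
spec = standard_scenario(seed=2, n_days=21)  # one away day + one shifted-sleep day
log = generate_routine_log(profile, spec)
placed, _ = preprocess(log, scenario_mapping(profile, spec))
counts = hourly_counts(placed)

reference, series, report, cap = analyze_counts(counts)  # auto min-dispersion window
print(f"reference window: {reference.window[0]} .. {reference.window[1]} ({reference.method})")
for day, value in zip(series.days, series.daily_index):
    marker = " <-- unusual" if any(o.date == day for o in report.outlier_days) else ""
    print(f"  {day}  similarity {value:+.3f}{marker}")
# days near 0.85-0.95 follow the routine; flagged days deviate strongly
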