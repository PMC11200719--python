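"""The three session indicators: count, duration, chewing frequency.

A session with a 6-second mid-session rest shows the rest-exclusion rule:
inter-chew gaps longer than 3 s are not rumination, so the reported
duration covers only the two active bouts.
"""

from chewtrack import (
    ChewSignalConfig,
    generate_chew_trajectory,
    rolling_chew_frequency,
    summarize_session,
    count_chews,
)

cfg = ChewSignalConfig(n_chews=60, rest_bouts=((30, 6.0),), seed=7)
trajectory, truth = generate_chew_trajectory(cfg)

summary = summarize_session(trajectory, rest_gap_s=3.0)

print(f"chew count:            {summary.chew_count}")
print(f"rumination duration:   {summary.rumination_duration_s:.2f} s")
print(f"chewing frequency:     {summary.chew_frequency_hz:.3f} Hz")
print(f"excluded rest:         {summary.excluded_rest_s:.2f} s")
for i, bout in enumerate(summary.bouts):
    print(f"bout {i}: {bout.start_s:.2f}-{bout.end_s:.2f} s, "
          f"{bout.chew_count} chews")

# Real-time frequency over a 10 s sliding window: it dips to ~0 during
# the rest and returns to ~1.2 Hz while the cow is actively chewing.
peaks = count_chews(trajectory)
grid, freq = rolling_chew_frequency(peaks.peak_times_s, window_s=10.0)
print(f"rolling frequency: min {freq.min():.2f} Hz, max {freq.max():.2f} Hz")
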