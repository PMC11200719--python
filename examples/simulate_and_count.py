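"""Generate a synthetic rumination session and count its chews.

The generator scripts a known number of jaw cycles into a nose-mouth
keypoint trajectory (with realistic per-cycle amplitude/period variation
and 1 px keypoint jitter); the counting pipeline then has to recover that
number from the trajectory alone.
"""

from chewtrack import ChewSignalConfig, count_chews, generate_chew_trajectory

cfg = ChewSignalConfig(n_chews=80, seed=42)
trajectory, truth = generate_chew_trajectory(cfg)

peaks = count_chews(trajectory)

print(f"scripted chews:   {truth.true_chew_count}")
print(f"counted chews:    {peaks.count}")
print(f"median threshold: {peaks.threshold_used:.2f} px")
print(f"rejected peaks:   {peaks.rejected}")

# The counted number should equal the scripted one; the threshold sits
# between the 30 px closed-mouth baseline and the ~45 px open-mouth crest,
# which is what lets it separate chews from rest-period wobble.
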