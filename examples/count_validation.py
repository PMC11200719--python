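"""Chew-count validation against manual tallies.

The bundled table holds ten video segments with the pipeline's assessed
chew count and a human observer's tally.  The report gives each video's
relative error (|assessed - measured| / assessed, in percent) plus the
mean and population standard deviation across videos.
"""

from pathlib import Path

import chewtrack
from chewtrack import count_report, read_manual_counts

table = Path(chewtrack.__file__).parent / "data" / "manual_chew_counts.csv"
counts = read_manual_counts(table)
report = count_report(counts, denominator="assessed")

print(report.to_string(index=False))
mean = report.loc[report.video_id == "mean", "relative_error_pct"].item()
print(f"\naccuracy: {100 - mean:.1f}%  (100 minus the mean relative error)")
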