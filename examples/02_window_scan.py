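"""Sliding-window diversity profile across a diversity peak.

Concatenates three synthetic segments — low diversity, high diversity,
low diversity — and scans theta_W in 2 kb windows moving by 150 bp, the
standard way to visualise localized balancing-selection peaks flanked by
ordinary sequence. The profile should peak in the central third.
"""

import numpy as np

from balsel.diversity import sliding_stats
from balsel.regionio import HaplotypeAlignment, Region
from balsel.synthgen import generate_neutral_region

segments = []
for i, theta_site in enumerate((4e-4, 4e-3, 4e-4)):
    aln, _ = generate_neutral_region(n=20, L=3000, theta=theta_site * 3000,
                                     seed=30 + i)
    segments.append(aln)

offsets = [0, 3000, 6000]
positions = np.concatenate([seg.positions + off
                            for seg, off in zip(segments, offsets)])
matrix = np.hstack([seg.haplotypes for seg in segments])
combined = HaplotypeAlignment(
    region=Region("synth", 0, 9000, "peak_demo"),
    haplotypes=matrix, positions=positions,
    populations=segments[0].populations)

table = sliding_stats(combined, window_bp=2000, step_bp=150)
peak = table.loc[table.theta_w.idxmax()]
print(table.head(8).to_string(index=False,
                              float_format=lambda v: f"{v:.5f}"))
print(f"...\n{len(table)} windows total")
print(f"max theta_W = {peak.theta_w * 1e4:.1f} x 1e-4 at "
      f"[{peak.start}, {peak.end}) — inside the high-diversity centre, "
      "as a balanced locus would appear against its flanks")
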