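"""Detect copy-number alterations against a panel of normals.

Pools simulated normal samples into a synthetic control, computes a
sample's per-100-kb-bin log2 copy ratio, and segments the track.
"""

import numpy as np

from labs_cfdna import bin_genome, build_panel, copy_ratio, segment_and_call, simulate_bin_counts

bins = bin_genome({"chr1": 100_000_000}, size=100_000)  # 1000 bins
panel = build_panel(
    [simulate_bin_counts(bins, total_reads=10**6, seed=s) for s in range(6)]
)

gain = ("chr1", 40_000_000, 60_000_000, 3.0)  # one extra copy over 20 Mb
sample = simulate_bin_counts(bins, [gain], tumor_fraction=0.4, total_reads=10**6, seed=42)
track = copy_ratio(sample, panel)
segments = segment_and_call(track, min_bins=10, threshold=0.15)

print(segments.to_string(index=False))
expected = np.log2(1 + 0.4 * (3 / 2 - 1))
print(f"closed-form expected gain ratio: log2(1.2) = {expected:.3f}")
# The gain segment's mean log2 ratio sits near log2(1.2) (slightly lower
# because total-count normalization spreads the extra reads genome-wide).
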