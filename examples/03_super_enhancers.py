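"""Stitch enhancer peaks and call super-enhancers by tangent cutoff.

Builds a rank-signal ("hockey stick") curve from toy enhancer peaks:
peaks within 12.5 kb are stitched into domains, domains are ranked by
total signal, and the cutoff sits where the scaled curve's tangent
reaches slope 1.  Everything above is a super-enhancer.
"""

import numpy as np

from chromadelta import GenomicInterval, stitch, super_cutoff

rng = np.random.default_rng(3)

# 60 scattered enhancer peaks: most modest, a few clusters of strong ones
peaks = []
for i in range(50):
    start = 40_000 * i
    peaks.append(GenomicInterval("chr1", start, start + 800,
                                 score=float(rng.gamma(2.0, 1.0))))
for c in range(3):  # strong clustered peaks -> super-enhancer candidates
    base = 2_100_000 + c * 100_000
    for j in range(4):
        peaks.append(GenomicInterval("chr1", base + j * 9_000,
                                     base + j * 9_000 + 800,
                                     score=float(rng.gamma(20.0, 1.5))))

stitched = stitch(peaks, max_gap=12_500)
threshold, ranked = super_cutoff(stitched)
supers = [e for e in ranked if e.is_super]

print(f"peaks: {len(peaks)}  stitched domains: {len(stitched)}")
print(f"signal threshold at tangent slope 1: {threshold:.1f}")
print(f"super-enhancers: {len(supers)}")
for e in supers:
    print(f"  {e.interval.chrom}:{e.interval.start}-{e.interval.end} "
          f"signal={e.signal:.1f} peaks={e.n_peaks}")
# The stitched clusters of strong peaks absorb most of the total signal and
# sit on the steep right arm of the curve, past the slope-1 tangent point.
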