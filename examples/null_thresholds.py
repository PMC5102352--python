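"""Build the simulation-based ΔSNP-index confidence band.

Under the null (no trait locus) the ΔSNP index of two 20-plant bulks
spreads with read depth; the 95% band per depth is the pair of empirical
null quantiles.  Deeper sequencing narrows the band.
"""

import numpy as np

from bulkmap import cibands

curve = cibands.null_delta_quantiles(
    bulk_size=20, depth_grid=np.arange(1, 101), n_replicates=10_000,
    confidence=0.95, seed=0,
)
print("depth   95% band")
for depth in (5, 10, 15, 25, 50, 100):
    lo, hi = curve.band_at(depth)
    print(f"{depth:>5}   [{lo[0]:+.3f}, {hi[0]:+.3f}]")
# A window's delta outside the band at its mean depth is called significant;
# the band never collapses to zero because bulks of 20 plants keep a
# sampling-variance floor even at infinite depth.
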