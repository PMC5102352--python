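"""Combine the two mapping prongs into a final candidate region.

Intersects a flanking-marker interval with a resequencing candidate
interval, reports the union span of several scan hits, and counts genes of
a small synthetic annotation falling in the final region.
"""

import numpy as np
import pandas as pd

from bulkmap import intervals as iv
from bulkmap.intervals import GenomicInterval

fine_map = GenomicInterval("A09", 18_255_838, 19_342_792, "fine_map")
reseq = GenomicInterval("A09", 17_830_000, 18_934_000, "bsa_scan")

final = iv.intersect(fine_map, reseq)
print(f"fine map:  {fine_map.chromosome}:{fine_map.start:,}-{fine_map.end:,}")
print(f"BSA scan:  {reseq.chromosome}:{reseq.start:,}-{reseq.end:,}")
print(f"final:     {final.chromosome}:{final.start:,}-{final.end:,}  "
      f"({iv.length_kb(final)} kb)")

scan_hits = [
    GenomicInterval("A09", 17_830_000, 18_930_000),
    GenomicInterval("A09", 20_530_000, 20_990_000),
    GenomicInterval("A09", 22_570_000, 26_090_000),
]
print(f"total scanned candidate span: {iv.total_span_mb(scan_hits)} Mb")

# synthetic gene annotation: one gene every ~25 kb across the region
rng = np.random.default_rng(0)
starts = np.arange(17_000_000, 20_000_000, 25_000) + rng.integers(0, 10_000, 120)
genes = pd.DataFrame(
    {"gene_id": [f"g{i:03d}" for i in range(120)], "chrom": "A09",
     "start": starts, "end": starts + rng.integers(500, 5_000, 120)}
)
print(f"genes overlapping the final region: {iv.count_genes(final, genes)}")
# Lengths use the end - start coordinate-difference convention; gene counts
# use any-overlap (>= 1 bp).
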