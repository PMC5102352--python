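"""Fine-map a locus from a backcross marker screen.

Builds a 1,739-plant screen over seven markers: five cosegregate with the
phenotype, the two flanks show 10 and 2 recombinants.  Prints each
marker's Kosambi distance, the 1:1 segregation test and the physical
interval between the flanking markers.
"""

import numpy as np
import pandas as pd

from bulkmap import linkmap
from bulkmap.linkmap import Marker, MarkerScreen

markers = [
    Marker("BrA10", "A09", 18_255_987, 18_255_838),
    Marker("BrA11", "A09", 18_407_330, 18_407_563),
    Marker("BrA13", "A09", 18_792_444, 18_792_152),
    Marker("BrA15", "A09", 19_115_029, 19_115_151),
    Marker("BrID10685", "A09", 19_342_792, 19_342_739),
]
recombinants = {"BrA10": 10, "BrID10685": 2}

rng = np.random.default_rng(7)
n = 1739
phenotype = np.where(rng.random(n) < 0.5, "yellow", "brown")
table = pd.DataFrame({"plant_id": [f"P{i:04d}" for i in range(n)], "phenotype": phenotype})
concordant = np.where(phenotype == "brown", "H", "A")
for m in markers:
    geno = concordant.copy()
    flip = rng.choice(n, size=recombinants.get(m.name, 0), replace=False)
    geno[flip] = np.where(geno[flip] == "H", "A", "H")
    table[m.name] = geno
screen = MarkerScreen(table=table, markers={m.name: m for m in markers})

counts = screen.table["phenotype"].value_counts()
chi2, p = linkmap.segregation_test(counts["yellow"], counts["brown"])
print(f"segregation {counts['yellow']}:{counts['brown']}  chi2={chi2:.3f}  p={p:.3f}")

results = linkmap.linkage_results(screen)
print(linkmap.format_text_map(results))

flank = linkmap.flanking_interval(results, boundary="outer")
print(
    f"locus between {flank.left_marker} and {flank.right_marker}: "
    f"{flank.chromosome}:{flank.start:,}-{flank.end:,}"
)
# cM values are Kosambi distances from k/n recombination fractions; "coseg"
# marks markers with zero recombinants, which only bound, not place, the locus.
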