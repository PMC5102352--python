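import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from bulkmap import popsim
from bulkmap.linkmap import Marker, MarkerScreen


@pytest.fixture
def two_chrom_genome():
    """Small two-chromosome genome: c1 carries the locus, c2 is unlinked."""
    return popsim.GenomeSpec(
        chromosomes=(("c1", 10_000_000), ("c2", 8_000_000)),
        snp_positions={
            "c1": np.arange(100_000, 10_000_001, 100_000),
            "c2": np.arange(100_000, 8_000_001, 200_000),
        },
        genetic_length={"c1": 1.0, "c2": 0.8},
    )


@pytest.fixture
def bc4_design():
    return popsim.CrossDesign(
        selection_locus=("c1", 5_000_000), n_backcrosses=4,
        bulk_size=20, population_size=200,
    )


def make_population(genome, design, donor_masks, phenotypes):
    """Assemble a Population directly from explicit donor matrices."""
    return popsim.Population(genome, design, donor_masks, np.asarray(phenotypes))


@pytest.fixture
def table1_screen():
    """Marker screen shaped like a published flanking-marker table: 1,739
    plants, five cosegregating markers bracketed by two flanks with 10 and
    2 recombinants."""
    markers = [
        Marker("BrA10", "A09", 18_255_987, 18_255_838),
        Marker("BrA11", "A09", 18_407_330, 18_407_563),
        Marker("BrA12", "A09", 18_570_940, 18_571_067),
        Marker("BrA13", "A09", 18_792_444, 18_792_152),
        Marker("BrA14", "A09", 18_962_948, 18_963_069),
        Marker("BrA15", "A09", 19_115_029, 19_115_151),
        Marker("BrID10685", "A09", 19_342_792, 19_342_739),
    ]
    n = 1739
    rng = np.random.default_rng(7)
    phenotype = np.where(rng.random(n) < 0.5, "yellow", "brown")
    table = pd.DataFrame(
        {"plant_id": [f"P{i:04d}" for i in range(n)], "phenotype": phenotype}
    )
    concordant = np.where(phenotype == "brown", "H", "A")
    recomb_counts = {"BrA10": 10, "BrID10685": 2}
    for m in markers:
        geno = concordant.copy()
        k = recomb_counts.get(m.name, 0)
        if k:
            flip = rng.choice(n, size=k, replace=False)
            geno[flip] = np.where(geno[flip] == "H", "A", "H")
        table[m.name] = geno
    return MarkerScreen(table=table, markers={m.name: m for m in markers})
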