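"""Simulator behaviour: crossover process, backcross genetics, bulks,
pooled depths and marker screens."""

import numpy as np
import pandas as pd
import pytest

from bulkmap import linkmap, popsim
from conftest import make_population


def test_genome_validation():
    with pytest.raises(ValueError, match="at least one chromosome"):
        popsim.GenomeSpec(chromosomes=(), snp_positions={})
    with pytest.raises(ValueError, match="strictly increasing"):
        popsim.GenomeSpec(
            chromosomes=(("c1", 100),),
            snp_positions={"c1": np.array([10, 10, 20])},
        )
    with pytest.raises(ValueError, match="outside"):
        popsim.GenomeSpec(
            chromosomes=(("c1", 100),), snp_positions={"c1": np.array([10, 200])}
        )


def test_selection_locus_must_be_a_snp(two_chrom_genome, bc4_design):
    bad = popsim.CrossDesign(selection_locus=("c1", 123), population_size=50)
    with pytest.raises(ValueError, match="not a SNP position"):
        popsim.simulate_cross(two_chrom_genome, bad, 0)
    with pytest.raises(ValueError, match="chromosome"):
        popsim.simulate_cross(
            two_chrom_genome,
            popsim.CrossDesign(selection_locus=("nope", 100_000)),
            0,
        )


def test_crossover_count_is_poisson_with_map_length_mean():
    rng = np.random.default_rng(11)
    xos = popsim.sample_crossovers(rng, morgans=1.0, length_bp=10**7, n=10_000)
    counts = np.array([x.size for x in xos])
    assert abs(counts.mean() - 1.0) < 0.03
    assert all((np.diff(x) >= 0).all() for x in xos[:100])


def test_zero_recombination_limit(two_chrom_genome):
    """With map length 0 the selected chromosome is inherited whole: every
    final plant is heterozygous across all of it or none, in ~1:1."""
    genome = popsim.GenomeSpec(
        chromosomes=two_chrom_genome.chromosomes,
        snp_positions={c: p.copy() for c, p in two_chrom_genome.snp_positions.items()},
        genetic_length={"c1": 0.0, "c2": 0.0},
    )
    design = popsim.CrossDesign(
        selection_locus=("c1", 5_000_000), n_backcrosses=4, population_size=400
    )
    pop = popsim.simulate_cross(genome, design, 5)
    per_plant = pop.donor["c1"].mean(axis=1)
    assert set(np.round(per_plant, 6)) <= {0.0, 1.0}
    het = (per_plant == 1.0).mean()
    assert abs(het - 0.5) < 4 * 0.5 / np.sqrt(400)


def test_bc1_unselected_heterozygote_fraction(two_chrom_genome):
    """A single backcross is unselected: expected heterozygote fraction 1/2
    at every SNP."""
    design = popsim.CrossDesign(
        selection_locus=("c1", 5_000_000), n_backcrosses=1, population_size=4000
    )
    pop = popsim.simulate_cross(two_chrom_genome, design, 2)
    for chrom in ("c1", "c2"):
        het = pop.donor[chrom].mean(axis=0)
        assert np.all(np.abs(het - 0.5) < 5 * 0.5 / np.sqrt(4000))


def test_heterozygosity_halves_per_backcross(two_chrom_genome):
    """Unlinked-locus heterozygosity has expectation 2^-n after n
    backcrosses; Monte-Carlo mean within 3 empirical SE."""
    design = popsim.CrossDesign(
        selection_locus=("c1", 5_000_000), n_backcrosses=4, population_size=100
    )
    snp = 10  # a SNP on the unlinked chromosome
    fractions = []
    for seed in range(150):
        pop = popsim.simulate_cross(two_chrom_genome, design, seed)
        fractions.append(pop.donor["c2"][:, snp].mean())
    fractions = np.array(fractions)
    sem = fractions.std(ddof=1) / np.sqrt(fractions.size)
    assert abs(fractions.mean() - 2.0**-4) < 3 * sem


def test_cross_is_deterministic_given_seed(two_chrom_genome, bc4_design):
    a = popsim.simulate_cross(two_chrom_genome, bc4_design, 42)
    b = popsim.simulate_cross(two_chrom_genome, bc4_design, 42)
    for chrom in two_chrom_genome.chromosome_names:
        np.testing.assert_array_equal(a.donor[chrom], b.donor[chrom])
    np.testing.assert_array_equal(a.phenotypes, b.phenotypes)


def test_phenotype_tracks_selection_locus(two_chrom_genome, bc4_design):
    pop = popsim.simulate_cross(two_chrom_genome, bc4_design, 1)
    locus_idx = np.searchsorted(two_chrom_genome.snp_positions["c1"], 5_000_000)
    carrier = pop.donor["c1"][:, locus_idx]
    assert np.all((pop.phenotypes == popsim.PHENO_DONOR) == carrier)
    ind = pop.individual(0)
    assert ind.genotype["c1"][locus_idx] == ("RD" if carrier[0] else "RR")


def test_bulk_allele_frequencies_at_locus(two_chrom_genome, bc4_design):
    """Before sequencing noise the donor-allele frequency at the selection
    locus is exactly 0 in the yellow bulk and 0.5 in the brown bulk."""
    pop = popsim.simulate_cross(two_chrom_genome, bc4_design, 3)
    yellow, brown = popsim.make_bulks(pop, bc4_design, 9)
    locus_idx = np.searchsorted(two_chrom_genome.snp_positions["c1"], 5_000_000)
    assert yellow.donor_allele_frequency("c1")[locus_idx] == 0.0
    assert brown.donor_allele_frequency("c1")[locus_idx] == 0.5


def test_bulks_forced_and_insufficient(two_chrom_genome):
    design = popsim.CrossDesign(
        selection_locus=("c1", 5_000_000), bulk_size=20, population_size=40
    )
    donor = {
        "c1": np.zeros((40, 100), dtype=bool),
        "c2": np.zeros((40, 40), dtype=bool),
    }
    donor["c1"][20:, :] = True
    phen = ["yellow"] * 20 + ["brown"] * 20
    pop = make_population(two_chrom_genome, design, donor, phen)
    yellow, brown = popsim.make_bulks(pop, design, 0)
    assert yellow.n_individuals == brown.n_individuals == 20
    assert not yellow.donor["c1"].any() and brown.donor["c1"].all()

    short = make_population(
        two_chrom_genome, design,
        {c: m[:25] for c, m in donor.items()}, phen[:25]
    )
    with pytest.raises(ValueError, match="brown"):
        popsim.make_bulks(short, design, 0)


def test_pool_depths_pure_and_intermediate(two_chrom_genome, bc4_design):
    donor = {
        "c1": np.zeros((20, 100), dtype=bool),
        "c2": np.zeros((20, 40), dtype=bool),
    }
    pure = make_population(two_chrom_genome, bc4_design, donor, ["yellow"] * 20)
    table = popsim.simulate_pool_depths(
        pure, two_chrom_genome, popsim.PoolDepthModel(15, 0.0), 1
    )
    assert (table["allele_D_count"] == 0).all()
    assert len(table) == 140  # every SNP emitted, zero-depth rows included

    half = {k: m.copy() for k, m in donor.items()}
    half["c1"][:, :] = True  # all heterozygous: f = 0.5
    pop = make_population(two_chrom_genome, bc4_design, half, ["brown"] * 20)
    deep = popsim.simulate_pool_depths(
        pop, two_chrom_genome, popsim.PoolDepthModel(1000, 0.0), 2
    )
    c1 = deep[deep["chrom"] == "c1"]
    frac = c1["allele_D_count"] / (c1["allele_R_count"] + c1["allele_D_count"])
    assert abs(frac.mean() - 0.5) < 0.01


def test_pool_depths_zero_depth_rows_kept(two_chrom_genome, bc4_design):
    donor = {
        "c1": np.zeros((20, 100), dtype=bool),
        "c2": np.zeros((20, 40), dtype=bool),
    }
    pop = make_population(two_chrom_genome, bc4_design, donor, ["yellow"] * 20)
    table = popsim.simulate_pool_depths(
        pop, two_chrom_genome, popsim.PoolDepthModel(0.5, 0.0), 3
    )
    totals = table["allele_R_count"] + table["allele_D_count"]
    assert (totals == 0).any()
    assert len(table) == 140


def test_marker_screen_cosegregation_and_errors(two_chrom_genome, bc4_design):
    pop = popsim.simulate_cross(two_chrom_genome, bc4_design, 6)
    at_locus = linkmap.Marker("L", "c1", 5_000_000, 5_000_000)
    screen = popsim.simulate_marker_screen(pop, [at_locus], bc4_design)
    k, n = linkmap.count_recombinants(screen, "L")
    assert (k, n) == (0, pop.n_individuals)
    with pytest.raises(ValueError, match="expected c1"):
        popsim.simulate_marker_screen(
            pop, [linkmap.Marker("X", "c2", 1_000_000, 1_000_000)], bc4_design
        )


def test_marker_screen_zero_recombination_columns_identical(two_chrom_genome):
    genome = popsim.GenomeSpec(
        chromosomes=two_chrom_genome.chromosomes,
        snp_positions={c: p.copy() for c, p in two_chrom_genome.snp_positions.items()},
        genetic_length={"c1": 0.0, "c2": 0.0},
    )
    design = popsim.CrossDesign(
        selection_locus=("c1", 5_000_000), n_backcrosses=4, population_size=100
    )
    pop = popsim.simulate_cross(genome, design, 8)
    markers = [
        linkmap.Marker("near", "c1", 5_000_000, 5_000_000),
        linkmap.Marker("far", "c1", 9_000_000, 9_000_000),
    ]
    screen = popsim.simulate_marker_screen(pop, markers, design)
    assert (screen.table["near"] == screen.table["far"]).all()


def test_bc1_marker_recombinant_mean_matches_map_distance():
    """In a single (unselected) backcross the marker-phenotype recombinant
    count is Binomial(n, r): at 1 cM and n = 1,739 the mean is ~17.4."""
    genome = popsim.GenomeSpec(
        chromosomes=(("c1", 10_000_000),),
        snp_positions={"c1": np.array([5_000_000, 5_100_000])},
        genetic_length={"c1": 1.0},  # 1 cM per 100 kb
    )
    design = popsim.CrossDesign(
        selection_locus=("c1", 5_000_000), n_backcrosses=1, population_size=1739
    )
    marker = linkmap.Marker("M", "c1", 5_100_000, 5_100_000)
    r = linkmap.kosambi_inverse(1.0)
    ks = []
    for seed in range(200):
        pop = popsim.simulate_cross(genome, design, seed)
        screen = popsim.simulate_marker_screen(pop, [marker], design)
        k, n = linkmap.count_recombinants(screen, "M")
        assert n == 1739
        ks.append(k)
    ks = np.asarray(ks, dtype=float)
    expected = 1739 * r  # 17.39
    assert abs(ks.mean() - expected) < 1.0


def test_bc4_recombinant_expectation_accumulates_over_meioses():
    """Over four backcross meioses the expected marker-phenotype recombinant
    fraction is (1-r)^3 · r + (1 - (1-r)^3)/2: the donor allele at the
    marker can be lost in any earlier generation, after which half the
    final plants are scored recombinant."""
    genome = popsim.GenomeSpec(
        chromosomes=(("c1", 10_000_000),),
        snp_positions={"c1": np.array([5_000_000, 5_100_000])},
        genetic_length={"c1": 1.0},
    )
    design = popsim.CrossDesign(
        selection_locus=("c1", 5_000_000), n_backcrosses=4, population_size=200
    )
    marker = linkmap.Marker("M", "c1", 5_100_000, 5_100_000)
    r = linkmap.kosambi_inverse(1.0)
    c = (1 - r) ** 3
    expected = c * r + (1 - c) / 2
    fracs = []
    for seed in range(300):
        pop = popsim.simulate_cross(genome, design, seed)
        screen = popsim.simulate_marker_screen(pop, [marker], design)
        k, n = linkmap.count_recombinants(screen, "M")
        fracs.append(k / n)
    fracs = np.asarray(fracs)
    sem = fracs.std(ddof=1) / np.sqrt(fracs.size)
    assert abs(fracs.mean() - expected) < 3 * sem
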