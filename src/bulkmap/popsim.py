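"""Backcross population and pooled-sequencing simulator.

Emulates the breeding design behind a bulked-segregant mapping study of a
single dominant/recessive locus: two inbred parents fixed for alternative
alleles at every marker SNP, repeated selective backcrossing to the
recurrent parent (retaining the donor allele at the selection locus each
generation), a final unselected generation that segregates ~1:1 at the
locus, phenotype bulks, and pooled short-read sequencing of the bulks.

Allele coding: every individual in a backcross programme carries, at each
SNP, either two recurrent-parent alleles (``RR``) or one recurrent and one
donor allele (``RD``); donor homozygotes cannot arise.  Genotypes are
therefore stored as a boolean "carries the donor allele" matrix.

Crossover model: per meiosis the number of crossovers on a chromosome is
Poisson with mean equal to the chromosome's genetic length in Morgans,
crossover positions are uniform on the physical chromosome (uniform cM/bp),
and there is no interference.  The model is deliberately the simplest one
consistent with the small map distances this kind of study estimates; it is
isolated in :func:`sample_crossovers` / :func:`_gamete_donor_masks` so it
can be swapped.

Phenotype model: the donor allele is dominant (donor carriers show the
donor-parent seed colour), which is the only coding consistent with a 1:1
phenotype ratio in a backcross to the non-donor parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linkmap import Marker, MarkerScreen

PHENO_RECURRENT = "yellow"  #: phenotype of RR individuals (recurrent parent)
PHENO_DONOR = "brown"  #: phenotype of RD individuals (donor allele dominant)

__all__ = [
    "GenomeSpec",
    "CrossDesign",
    "PoolDepthModel",
    "Individual",
    "Population",
    "sample_crossovers",
    "simulate_cross",
    "make_bulks",
    "simulate_pool_depths",
    "simulate_marker_screen",
    "PHENO_RECURRENT",
    "PHENO_DONOR",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome sizes, marker-SNP positions and genetic map lengths.

    Parameters
    ----------
    chromosomes
        ``[(name, length_bp), ...]``.
    snp_positions
        Per chromosome, a sorted integer array of 1-based SNP positions at
        which the two parents are fixed for alternative alleles.
    genetic_length
        Map length of each chromosome in Morgans.  A uniform cM/bp scale is
        assumed.  Zero is allowed and means no recombination.
    """

    chromosomes: tuple[tuple[str, int], ...]
    snp_positions: dict[str, np.ndarray] = field(repr=False)
    genetic_length: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.chromosomes) == 0:
            raise ValueError("genome must have at least one chromosome")
        lengths = dict(self.chromosomes)
        for chrom, length in lengths.items():
            pos = np.asarray(self.snp_positions.get(chrom, ()), dtype=np.int64)
            self.snp_positions[chrom] = pos
            if pos.size and (pos[0] < 1 or pos[-1] > length):
                raise ValueError(f"SNP positions outside [1, {length}] on {chrom}")
            if pos.size > 1 and not (np.diff(pos) > 0).all():
                raise ValueError(f"SNP positions not strictly increasing on {chrom}")
            morgans = self.genetic_length.setdefault(chrom, 1.0)
            if morgans < 0:
                raise ValueError(f"negative genetic length on {chrom}")

    @property
    def chromosome_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]


@dataclass(frozen=True)
class CrossDesign:
    """Breeding and bulking design of the mapping experiment.

    Defaults reproduce the study conditions this package models: four
    selective backcrosses (a BC4 population of 1,739 plants), a yellow
    recurrent parent, a brown donor parent, and phenotype bulks of
    20 plants each.
    """

    selection_locus: tuple[str, int]
    n_backcrosses: int = 4
    recurrent_parent: str = "Dahuang"
    donor_parent: str = "09A-126"
    bulk_size: int = 20
    population_size: int = 1739

    def __post_init__(self) -> None:
        if self.n_backcrosses < 1:
            raise ValueError("n_backcrosses must be >= 1")
        if self.bulk_size > self.population_size:
            raise ValueError("bulk_size cannot exceed population_size")


@dataclass(frozen=True)
class PoolDepthModel:
    """Pooled-sequencing depth/error model.

    ``mean_depth`` is the expected reads per site per pool (Poisson
    distributed); ``error_rate`` the symmetric per-read allele miscall
    probability.
    """

    mean_depth: float = 15.0
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


@dataclass(frozen=True)
class Individual:
    """Genotype codes (``RR``/``RD`` per SNP per chromosome) and phenotype."""

    genotype: dict[str, np.ndarray]
    phenotype: str


class Population:
    """A backcross population stored as donor-allele indicator matrices.

    ``donor[chrom]`` is a boolean ``(n_individuals, n_snps)`` array; ``True``
    means the individual is RD (heterozygous, carries the donor allele) at
    that SNP.
    """

    def __init__(
        self,
        genome: GenomeSpec,
        design: CrossDesign,
        donor: dict[str, np.ndarray],
        phenotypes: np.ndarray,
    ):
        self.genome = genome
        self.design = design
        self.donor = donor
        self.phenotypes = phenotypes

    @property
    def n_individuals(self) -> int:
        return int(self.phenotypes.size)

    def phenotype_counts(self) -> dict[str, int]:
        values, counts = np.unique(self.phenotypes, return_counts=True)
        out = {PHENO_RECURRENT: 0, PHENO_DONOR: 0}
        out.update(dict(zip(values.tolist(), counts.tolist())))
        return out

    def donor_allele_frequency(self, chrom: str) -> np.ndarray:
        """Per-SNP donor-allele frequency (each RD plant contributes 1/2)."""
        return 0.5 * self.donor[chrom].mean(axis=0)

    def individual(self, i: int) -> Individual:
        geno = {
            chrom: np.where(mask[i], "RD", "RR")
            for chrom, mask in self.donor.items()
        }
        return Individual(genotype=geno, phenotype=str(self.phenotypes[i]))

    def subset(self, indices: np.ndarray) -> "Population":
        donor = {c: m[indices] for c, m in self.donor.items()}
        return Population(self.genome, self.design, donor, self.phenotypes[indices])


def sample_crossovers(
    rng: np.random.Generator, morgans: float, length_bp: int, n: int
) -> list[np.ndarray]:
    """Draw crossover positions for ``n`` meioses on one chromosome.

    Counts are Poisson(``morgans``); positions uniform on ``(0, length_bp)``,
    returned sorted.  No interference.
    """
    counts = rng.poisson(morgans, size=n)
    return [np.sort(rng.uniform(0.0, length_bp, size=c)) for c in counts]


def _gamete_donor_masks(
    rng: np.random.Generator,
    parent_donor: np.ndarray,
    positions: np.ndarray,
    length_bp: int,
    morgans: float,
    n: int,
) -> np.ndarray:
    """Donor-allele masks of ``n`` gametes from a parent with donor set
    ``parent_donor`` (boolean per SNP).

    Chromatid 0 carries the parent's donor haplotype; the chromatid
    transmitted at each SNP follows the crossover mosaic.
    """
    out = np.empty((n, positions.size), dtype=bool)
    if positions.size == 0:
        return out
    start = rng.integers(0, 2, size=n)
    crossovers = sample_crossovers(rng, morgans, length_bp, n)
    for i, xo in enumerate(crossovers):
        if xo.size == 0:
            picked = np.full(positions.size, start[i])
        else:
            picked = (start[i] + np.searchsorted(xo, positions)) % 2
        out[i] = (picked == 0) & parent_donor
    return out


def _offspring(
    rng: np.random.Generator,
    genome: GenomeSpec,
    parent_donor: dict[str, np.ndarray],
    n: int,
) -> dict[str, np.ndarray]:
    """``n`` backcross offspring of a (partially) heterozygous parent and the
    recurrent parent; offspring donor set = gamete donor set."""
    return {
        chrom: _gamete_donor_masks(
            rng,
            parent_donor[chrom],
            genome.snp_positions[chrom],
            genome.length_of(chrom),
            genome.genetic_length[chrom],
            n,
        )
        for chrom in genome.chromosome_names
    }


def _locus_index(genome: GenomeSpec, locus: tuple[str, int]) -> tuple[str, int]:
    chrom, pos = locus
    if chrom not in genome.chromosome_names:
        raise ValueError(f"selection locus chromosome {chrom!r} not in genome")
    positions = genome.snp_positions[chrom]
    idx = int(np.searchsorted(positions, pos))
    if idx >= positions.size or positions[idx] != pos:
        raise ValueError(f"selection locus {chrom}:{pos} is not a SNP position")
    return chrom, idx


def simulate_cross(
    genome: GenomeSpec, design: CrossDesign, seed
) -> Population:
    """Simulate the selective-backcross programme and return the final,
    unselected, phenotyped generation.

    Starting from the F1 (heterozygous everywhere), each of the first
    ``n_backcrosses - 1`` generations is represented by one offspring kept
    heterozygous at the selection locus (drawn by rejection); the final
    backcross produces ``population_size`` unselected offspring.  Phenotype
    is donor-parent-like iff the individual carries the donor allele at the
    selection locus.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    loc_chrom, loc_idx = _locus_index(genome, design.selection_locus)

    parent = {
        chrom: np.ones(genome.snp_positions[chrom].size, dtype=bool)
        for chrom in genome.chromosome_names
    }
    for _ in range(design.n_backcrosses - 1):
        while True:  # rejection-sample one locus-heterozygous offspring
            batch = _offspring(rng, genome, parent, 8)
            het = np.flatnonzero(batch[loc_chrom][:, loc_idx])
            if het.size:
                i = int(het[0])
                parent = {c: m[i] for c, m in batch.items()}
                break

    donor = _offspring(rng, genome, parent, design.population_size)
    phenotypes = np.where(
        donor[loc_chrom][:, loc_idx], PHENO_DONOR, PHENO_RECURRENT
    )
    return Population(genome, design, donor, phenotypes)


def make_bulks(
    population: Population, design: CrossDesign, seed
) -> tuple[Population, Population]:
    """Sample the two phenotype bulks (recurrent-like, donor-like), each a
    uniform sample of ``bulk_size`` plants without replacement.

    Returns ``(yellow_bulk, brown_bulk)``.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    bulks = []
    for phenotype in (PHENO_RECURRENT, PHENO_DONOR):
        idx = np.flatnonzero(population.phenotypes == phenotype)
        if idx.size < design.bulk_size:
            raise ValueError(
                f"only {idx.size} {phenotype} plants available; "
                f"bulk_size is {design.bulk_size}"
            )
        chosen = np.sort(rng.choice(idx, size=design.bulk_size, replace=False))
        bulks.append(population.subset(chosen))
    return bulks[0], bulks[1]


def simulate_pool_depths(
    bulk: Population, genome: GenomeSpec, model: PoolDepthModel, seed
) -> pd.DataFrame:
    """Simulate pooled sequencing of one bulk.

    Per site: total depth ~ Poisson(``mean_depth``); each read reports the
    donor allele with probability ``f(1-e) + (1-f)e`` where ``f`` is the
    bulk's true donor-allele frequency and ``e`` the miscall rate.  Sites
    with zero drawn depth are emitted (downstream treats them as missing).

    Returns a table with columns ``chrom, pos, allele_R_count,
    allele_D_count``.
    """
    if bulk.n_individuals == 0:
        raise ValueError("bulk is empty")
    rng = np.random.default_rng(seed)
    frames = []
    e = model.error_rate
    for chrom in genome.chromosome_names:
        pos = genome.snp_positions[chrom]
        if pos.size == 0:
            continue
        f = bulk.donor_allele_frequency(chrom)
        depth = rng.poisson(model.mean_depth, size=pos.size)
        p_donor = f * (1.0 - e) + (1.0 - f) * e
        d_count = rng.binomial(depth, p_donor)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "allele_R_count": depth - d_count,
                    "allele_D_count": d_count,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_parent_depths(
    genome: GenomeSpec, model: PoolDepthModel, seed, donor_parent: bool
) -> pd.DataFrame:
    """Sequencing of an inbred parent: donor-allele frequency 1 (donor
    parent) or 0 (recurrent parent) at every SNP.  Same output columns as
    :func:`simulate_pool_depths`."""
    rng = np.random.default_rng(seed)
    f = 1.0 if donor_parent else 0.0
    frames = []
    e = model.error_rate
    for chrom in genome.chromosome_names:
        pos = genome.snp_positions[chrom]
        if pos.size == 0:
            continue
        depth = rng.poisson(model.mean_depth, size=pos.size)
        d_count = rng.binomial(depth, f * (1.0 - e) + (1.0 - f) * e)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "allele_R_count": depth - d_count,
                    "allele_D_count": d_count,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_marker_screen(
    population: Population,
    markers: list[Marker],
    design: CrossDesign,
) -> MarkerScreen:
    """Error-free genotype calls (``A`` = recurrent homozygote, ``H`` =
    heterozygote) for each plant at each marker, paired with phenotype.

    Each marker is scored at the SNP nearest its span midpoint; markers must
    lie on the selection-locus chromosome.
    """
    loc_chrom = design.selection_locus[0]
    positions = population.genome.snp_positions[loc_chrom]
    rows = {"plant_id": [f"P{i + 1:04d}" for i in range(population.n_individuals)],
            "phenotype": population.phenotypes}
    table = pd.DataFrame(rows)
    for marker in markers:
        if marker.chromosome != loc_chrom:
            raise ValueError(
                f"marker {marker.name} on {marker.chromosome}, "
                f"expected {loc_chrom}"
            )
        mid = marker.midpoint
        j = int(np.clip(np.searchsorted(positions, mid), 0, positions.size - 1))
        if j > 0 and abs(positions[j - 1] - mid) < abs(positions[j] - mid):
            j -= 1
        table[marker.name] = np.where(population.donor[loc_chrom][:, j], "H", "A")
    return MarkerScreen(table=table, markers={m.name: m for m in markers})
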