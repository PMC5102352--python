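"""End-to-end orchestration: simulate → polarize → index → thresholds →
candidate intervals → fine map → intersect.

Each run is driven by a :class:`RunConfig` (loadable from YAML) and a single
master seed; per-stage generators are spawned deterministically from the
master seed so any stage can be re-run in isolation.  All artifacts are
plain text (TSV/BED/JSON); plots are optional.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cibands, intervals, linkmap, popsim, snpindex, variantio

__all__ = ["RunConfig", "ConfigError", "run_bsa", "run_finemap", "stage_seed"]

POOLS = ("brown", "yellow")  # delta = brown − yellow

_STAGES = ("cross", "bulks", "pool_yellow", "pool_brown", "thresholds",
           "parent_ref", "parent_other")


class ConfigError(ValueError):
    """Invalid run configuration (raised before any I/O)."""


def stage_seed(master: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage seed derived from the master seed."""
    return np.random.SeedSequence([_STAGES.index(stage), int(master)])


@dataclass
class RunConfig:
    """Parameters of one BSA-scan run on simulated input.

    Defaults reproduce the study conditions the simulator models: one
    ~30 Mb chromosome, a BC4 population of 1,739 plants, bulks of 20, mean
    pool depth 15×, 1 Mb / 1 kb windows, a 95% band from 10,000 null
    replicates.
    """

    seed: int = 1
    chrom: str = "A09"
    chrom_length: int = 30_000_000
    n_snps: int = 3_000
    genetic_length_morgans: float = 1.0
    locus_bp: int = 18_500_000
    n_backcrosses: int = 4
    population_size: int = 1739
    bulk_size: int = 20
    mean_depth: float = 15.0
    error_rate: float = 0.001
    window: int = 1_000_000
    step: int = 1_000
    min_snps_per_window: int = 10
    low_index: float = 0.3
    low_depth: int = 7
    confidence: float = 0.95
    n_replicates: int = 10_000
    depth_grid_max: int = 60
    merge_gap_bp: int = 0
    make_plots: bool = False

    def validate(self) -> None:
        if self.window <= 0 or self.step <= 0 or self.window < self.step:
            raise ConfigError("window must be >= step and both positive")
        if not 0 < self.confidence < 1:
            raise ConfigError("confidence must be in (0, 1)")
        if self.bulk_size > self.population_size:
            raise ConfigError("bulk_size exceeds population_size")
        if not 1 <= self.locus_bp <= self.chrom_length:
            raise ConfigError("locus outside the chromosome")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def build_genome(config: RunConfig) -> tuple[popsim.GenomeSpec, popsim.CrossDesign]:
    """Genome with evenly spaced parent-diagnostic SNPs (locus snapped onto
    the nearest SNP) and the matching cross design."""
    positions = np.unique(
        np.linspace(1, config.chrom_length, config.n_snps).round().astype(np.int64)
    )
    locus = int(positions[np.argmin(np.abs(positions - config.locus_bp))])
    genome = popsim.GenomeSpec(
        chromosomes=((config.chrom, config.chrom_length),),
        snp_positions={config.chrom: positions},
        genetic_length={config.chrom: config.genetic_length_morgans},
    )
    design = popsim.CrossDesign(
        selection_locus=(config.chrom, locus),
        n_backcrosses=config.n_backcrosses,
        bulk_size=config.bulk_size,
        population_size=config.population_size,
    )
    return genome, design


def simulate_polarized_records(config: RunConfig):
    """Simulate the cross, bulks and pooled sequencing; return the polarized
    per-site table (with per-pool indices) plus the truth locus.

    The donor parent plays the reference role, so the measured allele is the
    recurrent parent's: pool measured count = recurrent-allele reads.
    """
    genome, design = build_genome(config)
    pop = popsim.simulate_cross(genome, design, stage_seed(config.seed, "cross"))
    yellow, brown = popsim.make_bulks(pop, design, stage_seed(config.seed, "bulks"))
    model = popsim.PoolDepthModel(config.mean_depth, config.error_rate)
    tables = {
        "yellow": popsim.simulate_pool_depths(
            yellow, genome, model, stage_seed(config.seed, "pool_yellow")
        ),
        "brown": popsim.simulate_pool_depths(
            brown, genome, model, stage_seed(config.seed, "pool_brown")
        ),
    }
    records = None
    for pool, tab in tables.items():
        part = tab.rename(
            columns={
                "allele_R_count": f"{pool}_measured",
            }
        )
        part[f"{pool}_depth"] = part[f"{pool}_measured"] + part.pop("allele_D_count")
        records = part if records is None else records.merge(part, on=["chrom", "pos"])
    records = snpindex.add_indices(records, POOLS)
    return records, genome, design


def run_bsa(config: RunConfig, outdir) -> dict:
    """Run the BSA scan end to end; write artifacts under ``outdir`` and
    return the JSON-ready summary."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    records, genome, design = simulate_polarized_records(config)
    n_input = len(records)
    kept, tally = snpindex.apply_filters(
        records, POOLS, snpindex.FilterRules(config.low_index, config.low_depth)
    )
    profile = snpindex.sliding_window_profile(
        kept,
        POOLS,
        window=config.window,
        step=config.step,
        min_snps=config.min_snps_per_window,
        chrom_lengths=dict(genome.chromosomes),
    )
    curve = cibands.null_delta_quantiles(
        design,
        depth_grid=np.arange(1, config.depth_grid_max + 1),
        n_replicates=config.n_replicates,
        confidence=config.confidence,
        seed=stage_seed(config.seed, "thresholds"),
    )
    flagged = cibands.flag_windows(profile, curve)
    candidates = cibands.extract_candidate_intervals(flagged, config.merge_gap_bp)

    flagged.to_csv(outdir / "windows.tsv", sep="\t", index=False)
    curve.to_tsv(outdir / "thresholds.tsv")
    intervals.write_bed(
        [
            intervals.GenomicInterval(c.chromosome, c.start, c.end, f"candidate_{i+1}")
            for i, c in enumerate(candidates)
        ],
        outdir / "candidates.bed",
    )
    if config.make_plots:
        from .plotting import manhattan

        manhattan(flagged, outdir / "manhattan.png")

    summary = {
        "seed": config.seed,
        "true_locus": {
            "chrom": design.selection_locus[0],
            "pos": design.selection_locus[1],
        },
        "n_sites_input": n_input,
        "filter_tally": tally,
        "n_sites_kept": len(kept),
        "n_windows": int(len(flagged)),
        "n_significant_windows": int(flagged["significant"].sum()),
        "candidates": [
            {
                "chrom": c.chromosome,
                "start": c.start,
                "end": c.end,
                "peak_delta": round(c.peak_delta, 6),
                "n_windows": c.n_windows,
            }
            for c in candidates
        ],
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def run_finemap(
    screen: linkmap.MarkerScreen,
    outdir,
    boundary: str = "outer",
    bsa_candidates: list[intervals.GenomicInterval] | None = None,
) -> dict:
    """Fine-map from a marker screen; optionally intersect the flanking
    interval with BSA candidate intervals."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = linkmap.linkage_results(screen)
    pheno = screen.table["phenotype"]
    chi2, p = linkmap.segregation_test(
        int((pheno == "yellow").sum()), int((pheno == "brown").sum())
    )
    flank = linkmap.flanking_interval(results, boundary=boundary)

    linkmap.write_genetic_map(results, outdir / "genetic_map.tsv")
    (outdir / "genetic_map.txt").write_text(linkmap.format_text_map(results))

    summary = {
        "segregation": {"chi2": round(chi2, 6), "p": round(p, 6)},
        "flanking_interval": {
            "chrom": flank.chromosome,
            "start": flank.start,
            "end": flank.end,
            "open_left": flank.open_left,
            "open_right": flank.open_right,
            "left_marker": flank.left_marker,
            "right_marker": flank.right_marker,
        },
        "markers": [
            {
                "marker": row["marker"],
                "k": int(row["k"]),
                "n": int(row["n"]),
                "distance_cM": None
                if np.isnan(row["distance_cM"])
                else round(float(row["distance_cM"]), 3),
            }
            for _, row in results.iterrows()
        ],
    }
    if bsa_candidates:
        fine = intervals.GenomicInterval(
            flank.chromosome, flank.start, flank.end, "fine_map"
        )
        hits = []
        for cand in bsa_candidates:
            inter = intervals.intersect(fine, cand)
            if inter is not None:
                hits.append(inter)
        best = max(hits, key=intervals.length_bp, default=None)
        summary["final_region"] = (
            None
            if best is None
            else {
                "chrom": best.chromosome,
                "start": best.start,
                "end": best.end,
                "length_kb": intervals.length_kb(best),
            }
        )
    with open(outdir / "finemap_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
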