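"""Allele-depth I/O and parent-based SNP polarization.

Input is a per-site, per-sample table of read counts for the two alleles of
a biallelic SNP — either a VCF with per-sample ``AD`` fields or an
equivalent TSV.  :func:`select_parent_homozygous` keeps the sites where the
two inbred parents are each homozygous for different alleles and annotates
every site with the *measured* allele: the allele of the parent that was
NOT chosen as reference.  Downstream SNP indices are fractions of reads
carrying that measured allele, so an offspring pool fixed for the reference
parent's allele has index 0 and one fixed for the other parent's allele has
index 1.

Coordinates are 1-based (VCF convention) everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

__all__ = [
    "ParentPolarity",
    "read_allele_depths",
    "write_allele_depth_vcf",
    "write_allele_depth_tsv",
    "select_parent_homozygous",
]


@dataclass(frozen=True)
class ParentPolarity:
    """Which parent's genome plays the reference role.

    SNP indices count reads carrying the other (non-reference) parent's
    allele; swapping ``reference_parent`` flips every downstream index i to
    1 − i.
    """

    reference_parent: str


def _check_sorted(df: pd.DataFrame, source: str) -> None:
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if pos.size > 1 and (np.diff(pos) <= 0).any():
            raise ValueError(f"{source}: positions not sorted on {chrom}")


def read_allele_depths(path, fmt: str | None = None) -> pd.DataFrame:
    """Read a per-sample allele-depth table from VCF or TSV.

    Returns a wide table with columns ``chrom, pos, ref, alt`` and, per
    sample, ``<sample>_ref`` / ``<sample>_alt`` read counts.  VCF sites
    with more than one ALT allele are skipped; the skip count is logged and
    stored in ``df.attrs["n_skipped_multiallelic"]``.  Missing depth fields
    and unsorted input raise ``ValueError``.
    """
    path = str(path)
    if fmt is None:
        fmt = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "vcf":
        df = _read_vcf(path)
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        required = {"chrom", "pos", "ref", "alt"}
        if not required.issubset(df.columns):
            raise ValueError(f"TSV lacks required columns {sorted(required)}")
        df.attrs["n_skipped_multiallelic"] = 0
    else:
        raise ValueError(f"unknown format {fmt!r}")
    _check_sorted(df, path)
    return df


def _read_vcf(path: str) -> pd.DataFrame:
    rows = []
    skipped = 0
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0],
            }
            for sample in samples:
                ad = rec.samples[sample].get("AD")
                if ad is None or len(ad) < 2 or ad[0] is None:
                    raise ValueError(
                        f"missing AD for sample {sample} at {rec.chrom}:{rec.pos}"
                    )
                row[f"{sample}_ref"] = int(ad[0])
                row[f"{sample}_alt"] = int(ad[1])
            rows.append(row)
    if skipped:
        log.info("skipped %d multi-allelic site(s)", skipped)
    df = pd.DataFrame(rows)
    df.attrs["n_skipped_multiallelic"] = skipped
    return df


def _vcf_header(df: pd.DataFrame, samples: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, grp in df.groupby("chrom", sort=False):
        header.contigs.add(str(chrom), length=int(grp["pos"].max()) + 1)
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for sample in samples:
        header.add_sample(sample)
    return header


def write_allele_depth_vcf(df: pd.DataFrame, path) -> None:
    """Write a wide allele-depth table (see :func:`read_allele_depths`) as a
    VCF with per-sample ``AD`` fields."""
    samples = [c[:-4] for c in df.columns if c.endswith("_ref")]
    header = _vcf_header(df, samples)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in df.itertuples(index=False):
            rec = vcf.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(str(row.ref), str(row.alt)),
            )
            for sample in samples:
                rec.samples[sample]["AD"] = (
                    int(getattr(row, f"{sample}_ref")),
                    int(getattr(row, f"{sample}_alt")),
                )
            vcf.write(rec)


def write_allele_depth_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def combine_samples(tables: dict[str, pd.DataFrame], ref: str, alt: str) -> pd.DataFrame:
    """Join per-sample ``chrom, pos, allele_R_count, allele_D_count`` tables
    (e.g. simulator output) into one wide allele-depth table.

    The recurrent (R) allele is written as ``ref`` and the donor (D) allele
    as ``alt`` at every site — adequate for simulated data where the actual
    bases carry no information.
    """
    out = None
    for sample, tab in tables.items():
        part = tab.rename(
            columns={"allele_R_count": f"{sample}_ref", "allele_D_count": f"{sample}_alt"}
        )
        out = part if out is None else out.merge(part, on=["chrom", "pos"], how="inner")
    out.insert(2, "ref", ref)
    out.insert(3, "alt", alt)
    return out


def select_parent_homozygous(
    df: pd.DataFrame,
    parent1: str,
    parent2: str,
    polarity: ParentPolarity,
    min_parent_depth: int = 4,
) -> pd.DataFrame:
    """Keep sites where both parents are homozygous for different alleles;
    polarize against the reference parent.

    "Homozygous" means every read supports one allele and total depth is at
    least ``min_parent_depth``.  The output keeps ``chrom, pos`` plus, for
    every non-parent sample, ``<sample>_measured`` (reads carrying the
    non-reference parent's allele) and ``<sample>_depth``; the measured
    allele base is recorded in ``measured_allele``.
    """
    for parent in (parent1, parent2):
        if f"{parent}_ref" not in df.columns:
            raise ValueError(f"unknown parent sample {parent!r}")
    if polarity.reference_parent not in (parent1, parent2):
        raise ValueError(
            f"reference parent {polarity.reference_parent!r} is not one of "
            f"({parent1!r}, {parent2!r})"
        )

    p1_ref = df[f"{parent1}_ref"].to_numpy()
    p1_alt = df[f"{parent1}_alt"].to_numpy()
    p2_ref = df[f"{parent2}_ref"].to_numpy()
    p2_alt = df[f"{parent2}_alt"].to_numpy()

    def hom_allele(ref_c, alt_c):
        depth = ref_c + alt_c
        ok = depth >= min_parent_depth
        # 0 = ref allele, 1 = alt allele, -1 = het or low depth
        allele = np.full(len(depth), -1, dtype=np.int8)
        allele[ok & (alt_c == 0)] = 0
        allele[ok & (ref_c == 0)] = 1
        return allele

    a1 = hom_allele(p1_ref, p1_alt)
    a2 = hom_allele(p2_ref, p2_alt)
    keep = (a1 >= 0) & (a2 >= 0) & (a1 != a2)

    other_parent = parent2 if polarity.reference_parent == parent1 else parent1
    measured_is_alt = (a2 if other_parent == parent2 else a1) == 1

    out = df.loc[keep, ["chrom", "pos"]].copy()
    out["measured_allele"] = np.where(
        measured_is_alt[keep], df.loc[keep, "alt"], df.loc[keep, "ref"]
    )
    pool_samples = [
        c[:-4]
        for c in df.columns
        if c.endswith("_ref") and c[:-4] not in (parent1, parent2)
    ]
    for sample in pool_samples:
        ref_c = df.loc[keep, f"{sample}_ref"].to_numpy()
        alt_c = df.loc[keep, f"{sample}_alt"].to_numpy()
        out[f"{sample}_measured"] = np.where(measured_is_alt[keep], alt_c, ref_c)
        out[f"{sample}_depth"] = ref_c + alt_c
    return out.reset_index(drop=True)
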