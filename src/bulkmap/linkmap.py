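"""Fine mapping from marker screens of a backcross population.

Given genotype calls (``A`` = recurrent homozygote, ``H`` = heterozygote,
missing allowed) and a seed-colour phenotype for every plant, this module
counts marker-trait recombinants, converts recombination fractions to map
distances with the Kosambi function, tests the expected 1:1 backcross
segregation, and derives the physical interval between the closest flanking
markers of a cosegregating marker block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Marker",
    "MarkerScreen",
    "FlankingInterval",
    "count_recombinants",
    "kosambi_distance",
    "kosambi_inverse",
    "segregation_test",
    "linkage_results",
    "flanking_interval",
]

GENOTYPE_CODES = ("A", "H")


@dataclass(frozen=True)
class Marker:
    """A PCR marker with its physical span (1-based, orientation-free)."""

    name: str
    chromosome: str
    start: int
    end: int

    @property
    def lo(self) -> int:
        return min(self.start, self.end)

    @property
    def hi(self) -> int:
        return max(self.start, self.end)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)


@dataclass
class MarkerScreen:
    """Genotype + phenotype table for a screened population.

    ``table`` has columns ``plant_id``, ``phenotype`` and one column per
    marker holding ``A``/``H`` or NA (missing call).  ``markers`` maps
    marker names to :class:`Marker` spans.
    """

    table: pd.DataFrame
    markers: dict[str, Marker]

    def __post_init__(self) -> None:
        for required in ("plant_id", "phenotype"):
            if required not in self.table.columns:
                raise ValueError(f"screen table lacks a {required!r} column")
        for name in self.markers:
            if name not in self.table.columns:
                raise ValueError(f"no genotype column for marker {name!r}")

    @property
    def marker_names(self) -> list[str]:
        """Marker names ordered by physical midpoint."""
        return sorted(self.markers, key=lambda n: self.markers[n].midpoint)

    def to_tsv(self, path) -> None:
        """Write the screen as one TSV; marker spans go into ``#marker``
        header comment lines so the file round-trips."""
        with open(path, "w") as fh:
            for name in self.marker_names:
                m = self.markers[name]
                fh.write(f"#marker\t{m.name}\t{m.chromosome}\t{m.start}\t{m.end}\n")
            self.table.to_csv(fh, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "MarkerScreen":
        markers: dict[str, Marker] = {}
        header_lines = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#marker\t"):
                    break
                _, name, chrom, start, end = line.rstrip("\n").split("\t")
                markers[name] = Marker(name, chrom, int(start), int(end))
                header_lines += 1
        table = pd.read_csv(
            path, sep="\t", skiprows=header_lines, na_values=["NA"], dtype={"plant_id": str}
        )
        return cls(table=table, markers=markers)


def count_recombinants(
    screen: MarkerScreen, marker_id: str, donor_dominant: bool = True
) -> tuple[int, int]:
    """Recombinant count ``k`` and informative plants ``n`` for one marker.

    With the donor allele dominant, a plant is recombinant when its marker
    genotype disagrees with its phenotype class: heterozygous but
    recurrent-phenotype, or recurrent-homozygous but donor-phenotype.
    Plants with a missing call are excluded from ``n``.
    """
    if marker_id not in screen.markers:
        raise KeyError(f"unknown marker {marker_id!r}")
    geno = screen.table[marker_id]
    informative = geno.notna()
    geno = geno[informative]
    pheno = screen.table.loc[informative, "phenotype"]
    donor_pheno = "brown" if donor_dominant else "yellow"
    is_donor_class = pheno == donor_pheno
    recombinant = ((geno == "H") & ~is_donor_class) | ((geno == "A") & is_donor_class)
    return int(recombinant.sum()), int(informative.sum())


def kosambi_distance(r) -> float:
    """Kosambi map distance in cM: ``d = 25·ln((1+2r)/(1−2r))``.

    Accepts scalars or arrays; requires ``0 <= r < 0.5`` (``r >= 0.5`` means
    the marker is unlinked and has no finite map distance).
    """
    r = np.asarray(r, dtype=float)
    if (r < 0).any() or (r >= 0.5).any():
        raise ValueError("recombination fraction must satisfy 0 <= r < 0.5")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d) -> float:
    """Recombination fraction from a Kosambi distance: ``r = tanh(2d/100)/2``."""
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(r) if r.ndim == 0 else r


def segregation_test(n_yellow: int, n_brown: int) -> tuple[float, float]:
    """1-df chi-square test of the 1:1 phenotype segregation expected in a
    backcross.  Returns ``(statistic, p_value)``."""
    if n_yellow + n_brown <= 0:
        raise ValueError("no plants")
    stat, p = stats.chisquare([n_yellow, n_brown])
    return float(stat), float(p)


def linkage_results(
    screen: MarkerScreen, donor_dominant: bool = True
) -> pd.DataFrame:
    """Per-marker linkage summary, ordered by physical midpoint.

    Columns: ``marker, chrom, span_lo, span_hi, k, n, r, distance_cM,
    cosegregating``.  ``distance_cM`` is the Kosambi distance of
    ``r = k/n``; markers with ``r >= 0.5`` get ``NaN`` (unlinked).
    """
    rows = []
    for name in screen.marker_names:
        m = screen.markers[name]
        k, n = count_recombinants(screen, name, donor_dominant)
        r = k / n if n else math.nan
        d = kosambi_distance(r) if 0 <= r < 0.5 else math.nan
        rows.append(
            {
                "marker": name,
                "chrom": m.chromosome,
                "span_lo": m.lo,
                "span_hi": m.hi,
                "k": k,
                "n": n,
                "r": r,
                "distance_cM": d,
                "cosegregating": k == 0,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FlankingInterval:
    """Physical interval bracketing a cosegregating marker block.

    ``open_left``/``open_right`` flag sides with no informative flanking
    marker; the corresponding bound falls back to the cosegregating block's
    own edge.
    """

    chromosome: str
    start: int
    end: int
    left_marker: str | None
    right_marker: str | None

    @property
    def open_left(self) -> bool:
        return self.left_marker is None

    @property
    def open_right(self) -> bool:
        return self.right_marker is None


def flanking_interval(
    results: pd.DataFrame, boundary: str = "outer"
) -> FlankingInterval:
    """Interval between the nearest nonzero-distance markers on each side of
    the cosegregating block.

    ``boundary`` selects which span coordinate of each flanking marker
    becomes the interval bound: ``"outer"`` (default) uses the coordinate
    facing away from the block — the convention that reproduces published
    flanking-marker intervals quoted from marker span tables — while
    ``"inner"`` uses the coordinate nearest the block.
    """
    if boundary not in ("outer", "inner"):
        raise ValueError("boundary must be 'outer' or 'inner'")
    res = results.sort_values(["span_lo", "span_hi"]).reset_index(drop=True)
    coseg = res.index[res["cosegregating"]]
    if coseg.empty:
        raise ValueError("no cosegregating marker; cannot place the locus")
    chrom = res.loc[coseg[0], "chrom"]
    first, last = coseg[0], coseg[-1]
    left = res.iloc[:first]
    left = left[~left["cosegregating"]]
    right = res.iloc[last + 1:]
    right = right[~right["cosegregating"]]

    if len(left):
        lm = left.iloc[-1]
        start = int(lm["span_lo"] if boundary == "outer" else lm["span_hi"])
        left_name = str(lm["marker"])
    else:
        start = int(res.loc[first, "span_lo"])
        left_name = None
    if len(right):
        rm = right.iloc[0]
        end = int(rm["span_hi"] if boundary == "outer" else rm["span_lo"])
        right_name = str(rm["marker"])
    else:
        end = int(res.loc[last, "span_hi"])
        right_name = None
    return FlankingInterval(str(chrom), start, end, left_name, right_name)


def write_genetic_map(results: pd.DataFrame, path) -> None:
    """Write the map as TSV (marker, cM to 3 decimals, k, n)."""
    out = results[["marker", "distance_cM", "k", "n"]].copy()
    out["distance_cM"] = out["distance_cM"].round(3)
    out.to_csv(path, sep="\t", index=False)


def format_text_map(results: pd.DataFrame) -> str:
    """Simple text rendering of the genetic map (marker, cM, physical Mb)."""
    lines = ["marker            cM     span (Mb)"]
    for _, row in results.iterrows():
        d = "coseg" if row["cosegregating"] else f"{row['distance_cM']:.3f}"
        lines.append(
            f"{row['marker']:<16} {d:>6}  "
            f"{row['span_lo'] / 1e6:.3f}-{row['span_hi'] / 1e6:.3f}"
        )
    return "\n".join(lines) + "\n"
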