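"""Simulation-based confidence bands for the ΔSNP index and candidate
interval extraction.

Under the null hypothesis (no trait locus) the two bulks are exchangeable
samples of the segregating population, so the ΔSNP index fluctuates around
zero with a spread set by two sampling layers: which plants entered each
bulk (bulk-size component) and which reads were drawn (depth component).
:func:`null_delta_quantiles` reproduces both layers per replicate: draw
each bulk's heterozygote count Binomial(bulk_size, het_prob), hence its
allele frequency; draw each pool's read depth zero-truncated Poisson around
the grid depth (mirroring the pooled-sequencing depth model, and giving the
null delta a near-continuous distribution, which a fixed read count would
not); draw the measured-allele reads binomially; difference the two pools'
indices.  Empirical quantiles at (1−c)/2 and 1−(1−c)/2 form the band.

``het_prob`` defaults to 1/2 — at an unlinked locus a backcross plant
passed through the final unselected cross is heterozygous with probability
at most 1/2, and 1/2 matches the 1:1 segregation the selected locus itself
shows, making the default band conservative for loci partially purged by
earlier backcrosses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdCurve",
    "CandidateInterval",
    "null_delta_quantiles",
    "flag_windows",
    "extract_candidate_intervals",
]


@dataclass
class ThresholdCurve:
    """Depth-indexed null quantile band of the ΔSNP index."""

    depths: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    confidence: float
    n_replicates: int
    seed: int | None = None
    het_prob: float = 0.5
    bulk_size: int = 20

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.depths.size == 0:
            raise ValueError("empty threshold curve")

    def band_at(self, depth) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) at the nearest grid depth; vectorized."""
        depth = np.atleast_1d(np.asarray(depth, dtype=float))
        j = np.searchsorted(self.depths, depth)
        j = np.clip(j, 1, self.depths.size - 1) if self.depths.size > 1 else np.zeros_like(j)
        if self.depths.size > 1:
            pick_left = np.abs(depth - self.depths[j - 1]) <= np.abs(self.depths[j] - depth)
            j = np.where(pick_left, j - 1, j)
        return self.lower[j], self.upper[j]

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"depth": self.depths, "lower": self.lower, "upper": self.upper}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, confidence: float, n_replicates: int) -> "ThresholdCurve":
        df = pd.read_csv(path, sep="\t")
        return cls(
            depths=df["depth"].to_numpy(),
            lower=df["lower"].to_numpy(),
            upper=df["upper"].to_numpy(),
            confidence=confidence,
            n_replicates=n_replicates,
        )


def sample_null_deltas(
    rng: np.random.Generator,
    bulk_size: int,
    depth,
    n: int,
    het_prob: float = 0.5,
) -> np.ndarray:
    """Null ΔSNP-index replicates at mean depth(s) ``depth``.

    ``depth`` may be a scalar or an array broadcast against ``n``
    replicates; returns shape ``(n_depths, n)`` for an array, ``(n,)`` for
    a scalar.
    """
    depth = np.asarray(depth, dtype=float)
    scalar = depth.ndim == 0
    depth = np.atleast_1d(depth)
    if (depth <= 0).any():
        raise ValueError("depths must be positive")
    shape = (2, depth.size, n)
    k = rng.binomial(bulk_size, het_prob, size=shape)
    f = k / (2.0 * bulk_size)
    d = rng.poisson(depth[None, :, None], size=shape)
    while True:  # zero-truncated: a sequenced site has >= 1 read
        zero = d == 0
        if not zero.any():
            break
        d[zero] = rng.poisson(np.broadcast_to(depth[None, :, None], shape)[zero])
    reads = rng.binomial(d, f)
    idx = reads / d
    delta = idx[0] - idx[1]
    return delta[0] if scalar else delta


def null_delta_quantiles(
    design=None,
    depth_grid=None,
    n_replicates: int = 10_000,
    confidence: float = 0.95,
    seed=None,
    het_prob: float = 0.5,
    bulk_size: int | None = None,
) -> ThresholdCurve:
    """Monte-Carlo null quantile band of the ΔSNP index per depth.

    ``design`` supplies ``bulk_size`` (or pass ``bulk_size`` directly);
    ``depth_grid`` defaults to 1..100.  Deterministic given ``seed``.
    """
    if bulk_size is None:
        if design is None:
            raise ValueError("need a CrossDesign or an explicit bulk_size")
        bulk_size = design.bulk_size
    if depth_grid is None:
        depth_grid = np.arange(1, 101)
    depth_grid = np.asarray(depth_grid, dtype=np.int64)
    if (depth_grid <= 0).any():
        raise ValueError("depth grid must be positive")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    delta = sample_null_deltas(rng, bulk_size, depth_grid, n_replicates, het_prob)
    alpha = (1.0 - confidence) / 2.0
    lower, upper = np.quantile(delta, [alpha, 1.0 - alpha], axis=1)
    return ThresholdCurve(
        depths=depth_grid,
        lower=lower,
        upper=upper,
        confidence=confidence,
        n_replicates=n_replicates,
        seed=seed,
        het_prob=het_prob,
        bulk_size=bulk_size,
    )


def flag_windows(profile: pd.DataFrame, curve: ThresholdCurve) -> pd.DataFrame:
    """Mark windows whose ΔSNP index falls outside the null band at their
    representative depth.

    Windows flagged ``low_snp`` (or without a delta) are never significant.
    Adds ``lower``, ``upper`` and ``significant`` columns.
    """
    out = profile.copy()
    depth = out["depth_mean"].to_numpy(dtype=float)
    lower, upper = curve.band_at(np.where(np.isnan(depth), curve.depths[0], depth))
    out["lower"] = lower
    out["upper"] = upper
    delta = out["delta"].to_numpy(dtype=float)
    qualified = ~out["low_snp"].to_numpy() & ~np.isnan(delta)
    out["significant"] = qualified & ((delta < lower) | (delta > upper))
    return out


@dataclass(frozen=True)
class CandidateInterval:
    """A maximal run of significant windows, as a physical interval."""

    chromosome: str
    start: int
    end: int
    peak_delta: float
    n_windows: int
    merge_gap_bp: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start > end")


def extract_candidate_intervals(
    flagged: pd.DataFrame, merge_gap_bp: int = 0
) -> list[CandidateInterval]:
    """Candidate intervals = unions of consecutive significant windows.

    Runs separated by at most ``merge_gap_bp`` (gap between the end of one
    run's span and the start of the next) are merged.  Output is sorted by
    chromosome and start.
    """
    out: list[CandidateInterval] = []
    for chrom, grp in flagged.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        sig = grp[grp["significant"]]
        if sig.empty:
            continue
        runs: list[dict] = []
        starts = grp["start"].to_numpy()
        flags = grp["significant"].to_numpy()
        # run boundaries over consecutive window rows
        boundaries = np.flatnonzero(np.diff(flags.astype(np.int8)))
        edges = np.concatenate(([0], boundaries + 1, [flags.size]))
        for a, b in zip(edges[:-1], edges[1:]):
            if not flags[a]:
                continue
            block = grp.iloc[a:b]
            runs.append(
                {
                    "start": int(block["start"].min()),
                    "end": int(block["end"].max()),
                    "peak": float(
                        block["delta"].iloc[block["delta"].abs().argmax()]
                    ),
                    "n": int(len(block)),
                }
            )
        merged = [runs[0]]
        for run in runs[1:]:
            prev = merged[-1]
            if run["start"] - prev["end"] - 1 <= merge_gap_bp:
                prev["end"] = max(prev["end"], run["end"])
                prev["n"] += run["n"]
                if abs(run["peak"]) > abs(prev["peak"]):
                    prev["peak"] = run["peak"]
            else:
                merged.append(run)
        for run in merged:
            out.append(
                CandidateInterval(
                    chromosome=str(chrom),
                    start=run["start"],
                    end=run["end"],
                    peak_delta=run["peak"],
                    n_windows=run["n"],
                    merge_gap_bp=merge_gap_bp,
                )
            )
    out.sort(key=lambda iv: (iv.chromosome, iv.start))
    return out
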