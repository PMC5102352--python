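"""SNP-index computation, filtering, and sliding-window ΔSNP-index profiles.

The SNP index of a pool at a polarized site is the fraction of its reads
carrying the measured (non-reference-parent) allele; it is missing (NaN)
when the pool has no reads there.  Two filters remove uninformative sites:
(a) index < ``low_index`` with depth < ``low_depth`` in *both* pools —
low-coverage sites drifting near the reference allele in both bulks — and
(b) a missing index in *either* pool.  The genome is then scanned with a
sliding window (default 1 Mb window, 1 kb step): per window the unweighted
mean index of each pool and their difference, the ΔSNP index, are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "FilterRules",
    "compute_snp_index",
    "add_indices",
    "apply_filters",
    "sliding_window_profile",
]

MISSING = float("nan")


@dataclass(frozen=True)
class FilterRules:
    """Thresholds of the low-signal filter; defaults are the standard ones
    for ~15× pooled data (index < 0.3 together with depth < 7)."""

    low_index: float = 0.3
    low_depth: int = 7


def compute_snp_index(measured, total):
    """Per-site index = measured-allele reads / total reads (NaN at depth 0).

    Vectorized; raises when a measured count exceeds its total.
    """
    measured = np.asarray(measured, dtype=float)
    total = np.asarray(total, dtype=float)
    if (measured > total).any():
        raise ValueError("measured allele count exceeds total depth")
    if (measured < 0).any() or (total < 0).any():
        raise ValueError("negative read counts")
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(total > 0, measured / np.where(total > 0, total, 1), MISSING)
    return float(idx) if idx.ndim == 0 else idx


def add_indices(polarized: pd.DataFrame, pools: tuple[str, str]) -> pd.DataFrame:
    """Add ``<pool>_index`` columns to a polarized site table (which has
    ``<pool>_measured`` and ``<pool>_depth`` columns)."""
    out = polarized.copy()
    for pool in pools:
        out[f"{pool}_index"] = compute_snp_index(
            out[f"{pool}_measured"].to_numpy(), out[f"{pool}_depth"].to_numpy()
        )
    return out


def apply_filters(
    records: pd.DataFrame,
    pools: tuple[str, str],
    rules: FilterRules = FilterRules(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the two removal rules; return the kept records and a tally.

    A site is removed iff (a) in both pools index < ``rules.low_index`` AND
    depth < ``rules.low_depth``, or (b) its index is missing in either
    pool.  Missingness is judged first, so the tally attributes each removed
    site to exactly one rule and sums to input − output.
    """
    idx = {p: records[f"{p}_index"].to_numpy() for p in pools}
    depth = {p: records[f"{p}_depth"].to_numpy() for p in pools}
    missing_either = np.isnan(idx[pools[0]]) | np.isnan(idx[pools[1]])
    low_both = np.ones(len(records), dtype=bool)
    for p in pools:
        low_both &= (idx[p] < rules.low_index) & (depth[p] < rules.low_depth)
    low_both &= ~missing_either
    tally = {
        "low_index_low_depth_both_pools": int(low_both.sum()),
        "missing_index_either_pool": int(missing_either.sum()),
    }
    kept = records.loc[~(low_both | missing_either)].reset_index(drop=True)
    return kept, tally


def sliding_window_profile(
    records: pd.DataFrame,
    pools: tuple[str, str],
    window: int = 1_000_000,
    step: int = 1_000,
    min_snps: int = 10,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window means of the two pools' SNP indices and their delta.

    Windows start at 1, 1+step, 1+2·step, … per chromosome (1-based
    inclusive spans); the scan extends to the chromosome length when given,
    else to the last SNP.  Trailing windows clipped at the chromosome end
    are flagged ``partial``.  ΔSNP index = mean index of ``pools[0]`` −
    mean index of ``pools[1]``.  Windows holding fewer than ``min_snps``
    SNPs are flagged ``low_snp``; interval calling ignores them.
    ``depth_mean`` is the mean per-SNP, per-pool depth of member SNPs (the
    representative depth used for threshold lookup).
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if window < step:
        raise ValueError("window must be >= step")
    frames = []
    for chrom, grp in records.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if not (np.diff(pos) > 0).all():
            raise ValueError(f"records not sorted by position on {chrom}")
        chrom_end = int(chrom_lengths[chrom]) if chrom_lengths else int(pos.max())
        starts = np.arange(1, chrom_end + 1, step, dtype=np.int64)
        ends = np.minimum(starts + window - 1, chrom_end)
        left = np.searchsorted(pos, starts, side="left")
        right = np.searchsorted(pos, ends, side="right")
        n = right - left
        out = pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": ends, "n_snps": n}
        )
        safe_n = np.where(n > 0, n, 1)
        with np.errstate(invalid="ignore"):
            for p in pools:
                cum = np.concatenate(([0.0], np.cumsum(grp[f"{p}_index"].to_numpy())))
                out[f"{p}_index"] = np.where(n > 0, (cum[right] - cum[left]) / safe_n, np.nan)
            depth_sum = sum(grp[f"{p}_depth"].to_numpy() for p in pools) / len(pools)
            cumd = np.concatenate(([0.0], np.cumsum(depth_sum)))
            out["depth_mean"] = np.where(n > 0, (cumd[right] - cumd[left]) / safe_n, np.nan)
        out["delta"] = out[f"{pools[0]}_index"] - out[f"{pools[1]}_index"]
        out["low_snp"] = n < min_snps
        out["partial"] = (ends - starts + 1) < window
        frames.append(out)
    return pd.concat(frames, ignore_index=True)
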