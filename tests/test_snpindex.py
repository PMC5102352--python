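"""SNP-index arithmetic, the two removal rules, and the sliding-window
profile."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bulkmap import snpindex
from bulkmap.snpindex import FilterRules

POOLS = ("brown", "yellow")


def make_records(pos, brown, yellow, depth_brown=20, depth_yellow=20, chrom="c1"):
    n = len(pos)
    as_arr = lambda v: np.full(n, v) if np.isscalar(v) else np.asarray(v)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "brown_index": as_arr(brown),
            "yellow_index": as_arr(yellow),
            "brown_depth": as_arr(depth_brown),
            "yellow_depth": as_arr(depth_yellow),
        }
    )
    return df


class TestComputeSnpIndex:
    @pytest.mark.parametrize(
        "measured,total,expected", [(5, 20, 0.25), (0, 12, 0.0), (7, 7, 1.0)]
    )
    def test_values(self, measured, total, expected):
        assert snpindex.compute_snp_index(measured, total) == expected

    def test_zero_depth_is_missing(self):
        assert math.isnan(snpindex.compute_snp_index(0, 0))

    def test_measured_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            snpindex.compute_snp_index(5, 4)

    @given(st.integers(0, 500), st.integers(0, 500))
    def test_index_bounded(self, a, extra):
        idx = snpindex.compute_snp_index(a, a + extra)
        assert math.isnan(idx) or 0.0 <= idx <= 1.0


class TestApplyFilters:
    def test_enumerated_rules(self):
        # site 0: low+shallow in both pools -> removed by rule (a)
        # site 1: low+shallow in one pool only -> retained
        # site 2: missing in one pool -> removed by rule (b)
        # site 3: clean -> retained
        df = make_records(
            [100, 200, 300, 400],
            brown=[0.2, 0.2, np.nan, 0.9],
            yellow=[0.1, 0.6, 0.8, 0.95],
            depth_brown=[5, 5, 0, 18],
            depth_yellow=[6, 20, 15, 22],
        )
        kept, tally = snpindex.apply_filters(df, POOLS)
        assert list(kept["pos"]) == [200, 400]
        assert tally == {
            "low_index_low_depth_both_pools": 1,
            "missing_index_either_pool": 1,
        }

    def test_boundary_values_not_removed(self):
        # index exactly at 0.3 or depth exactly 7 fails the strict < rule
        df = make_records(
            [100, 200], brown=[0.3, 0.1], yellow=[0.1, 0.1],
            depth_brown=[5, 7], depth_yellow=[5, 5],
        )
        kept, _ = snpindex.apply_filters(df, POOLS)
        assert len(kept) == 2

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 30), st.integers(0, 30),
                st.integers(0, 30), st.integers(0, 30),
            ),
            max_size=40,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_tally_accounts_for_every_removal(self, sites):
        pos = np.arange(1, len(sites) + 1) * 10
        b_m = np.array([s[0] for s in sites])
        b_d = b_m + np.array([s[1] for s in sites])
        y_m = np.array([s[2] for s in sites])
        y_d = y_m + np.array([s[3] for s in sites])
        df = make_records(
            pos,
            brown=snpindex.compute_snp_index(b_m, b_d) if len(sites) else [],
            yellow=snpindex.compute_snp_index(y_m, y_d) if len(sites) else [],
            depth_brown=b_d, depth_yellow=y_d,
        )
        kept, tally = snpindex.apply_filters(df, POOLS)
        assert len(kept) + sum(tally.values()) == len(df)


class TestSlidingWindow:
    def test_single_window_mean(self):
        df = make_records([10, 20, 30], brown=[0.4, 0.5, 0.6], yellow=0.2)
        prof = snpindex.sliding_window_profile(
            df, POOLS, window=100, step=100, min_snps=1
        )
        assert prof.loc[0, "brown_index"] == pytest.approx(0.5)
        assert prof.loc[0, "delta"] == pytest.approx(0.3)
        assert prof.loc[0, "n_snps"] == 3

    def test_empty_window_flagged(self):
        df = make_records([10, 250], brown=0.5, yellow=0.5)
        prof = snpindex.sliding_window_profile(
            df, POOLS, window=100, step=100, min_snps=1
        )
        middle = prof[(prof["start"] == 101)]
        assert middle["n_snps"].item() == 0
        assert middle["low_snp"].item()
        assert math.isnan(middle["delta"].item())

    def test_invalid_geometry_rejected(self):
        df = make_records([10], brown=0.5, yellow=0.5)
        for window, step in ((0, 1), (10, 20), (-5, 1)):
            with pytest.raises(ValueError):
                snpindex.sliding_window_profile(df, POOLS, window=window, step=step)

    def test_polarity_flip_negates_delta(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1, 5000), 80, replace=False))
        b, y = rng.random(80), rng.random(80)
        prof = snpindex.sliding_window_profile(
            make_records(pos, b, y), POOLS, window=500, step=100, min_snps=1
        )
        flipped = snpindex.sliding_window_profile(
            make_records(pos, 1 - b, 1 - y), POOLS, window=500, step=100, min_snps=1
        )
        np.testing.assert_allclose(flipped["delta"], -prof["delta"], atol=1e-12)
        np.testing.assert_allclose(
            flipped["brown_index"], 1 - prof["brown_index"], atol=1e-12
        )

    def test_window_mean_bounded_by_members(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(np.arange(1, 3000), 60, replace=False))
        b = rng.random(60)
        df = make_records(pos, b, 0.0)
        prof = snpindex.sliding_window_profile(
            df, POOLS, window=400, step=150, min_snps=1
        )
        for _, row in prof[prof["n_snps"] > 0].iterrows():
            members = b[(pos >= row["start"]) & (pos <= row["end"])]
            assert members.min() - 1e-12 <= row["brown_index"] <= members.max() + 1e-12

    def test_matches_naive_oracle(self):
        """Cumulative-sum windows equal a direct per-window scan."""
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = rng.integers(5, 100)
            pos = np.sort(rng.choice(np.arange(1, 2000), n, replace=False))
            df = make_records(pos, rng.random(n), rng.random(n))
            window = int(rng.integers(50, 600))
            step = int(rng.integers(10, window + 1))
            prof = snpindex.sliding_window_profile(
                df, POOLS, window=window, step=step, min_snps=1
            )
            for _, row in prof.iterrows():
                mask = (pos >= row["start"]) & (pos <= row["end"])
                assert mask.sum() == row["n_snps"]
                if mask.any():
                    assert row["brown_index"] == pytest.approx(
                        df["brown_index"].to_numpy()[mask].mean()
                    )
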