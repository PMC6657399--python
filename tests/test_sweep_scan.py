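"""Window statistics: pooled heterozygosity, FST, Z-scores, outliers."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from poolsweep.sweep_scan import (
    ScanConfig,
    extract_outliers,
    make_windows,
    pooled_heterozygosity,
    scan,
    snp_fst,
    window_fst,
    z_transform,
)
from poolsweep.types import ContigSpec
from .conftest import make_sites


class TestPooledHeterozygosity:
    def test_fixed_windows_are_zero(self):
        sites = make_sites([("c", 1, 50.0, 10, 0, 5, 5), ("c", 2, 50.0, 8, 0, 5, 5)])
        assert pooled_heterozygosity(sites, "A") == 0.0

    def test_maximum_half_at_equal_sums(self):
        sites = make_sites([("c", 1, 50.0, 10, 10, 1, 1)])
        assert pooled_heterozygosity(sites, "A") == 0.5

    def test_mixed_counts(self):
        sites = make_sites([
            ("c", 1, 50.0, 30, 5, 1, 1),
            ("c", 2, 50.0, 20, 20, 1, 1),
            ("c", 3, 50.0, 40, 0, 1, 1),
        ])
        # a=90, b=25 -> 2*90*25 / 115^2
        assert pooled_heterozygosity(sites, "A") == pytest.approx(
            4500 / 13225, rel=1e-12
        )

    def test_zero_total_reads_is_nan_not_zero(self):
        sites = make_sites([("c", 1, 50.0, 0, 0, 5, 5)])
        assert math.isnan(pooled_heterozygosity(sites, "A"))
        assert pooled_heterozygosity(sites, "B") == 0.5

    @given(st.lists(
        st.tuples(st.integers(0, 500), st.integers(0, 500)),
        min_size=1, max_size=30,
    ).filter(lambda rows: sum(a + b for a, b in rows) > 0))
    def test_bounded_by_half_with_equality_iff_balanced(self, rows):
        sites = make_sites(
            [("c", i + 1, 50.0, a, b, 1, 1) for i, (a, b) in enumerate(rows)]
        )
        hp = pooled_heterozygosity(sites, "A")
        assert 0.0 <= hp <= 0.5
        a = sum(r[0] for r in rows)
        b = sum(r[1] for r in rows)
        assert (hp == 0.5) == (a == b)


class TestSnpFst:
    def test_hand_evaluated_hudson_site(self):
        # minor fractions 0.8 vs 0.2, 20 haploids per group
        num, den = snp_fst(2, 8, 8, 2, haploids_a=20, haploids_b=20)
        assert num == pytest.approx(0.36 - 2 * 0.16 / 19, rel=1e-12)
        assert den == pytest.approx(0.68, rel=1e-12)
        assert num / den == pytest.approx(0.5046439, rel=1e-6)

    def test_fixed_difference_approaches_one(self):
        num, den = snp_fst(0, 30, 30, 0, haploids_a=10_000, haploids_b=10_000)
        assert den == pytest.approx(1.0)
        assert num / den == pytest.approx(1.0, abs=1e-3)

    def test_equal_frequencies_give_nonpositive_numerator(self):
        num, _ = snp_fst(12, 8, 12, 8, haploids_a=20, haploids_b=20)
        assert num <= 0

    def test_haploid_size_must_exceed_one(self):
        with pytest.raises(ValueError, match="haploid"):
            snp_fst(5, 5, 5, 5, haploids_a=1, haploids_b=20)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            snp_fst(0, 0, 5, 5)

    def test_wright_mean_fixed_difference_is_one(self):
        num, den = snp_fst(0, 30, 30, 0, estimator="wright_mean")
        assert num / den == pytest.approx(1.0)


class TestWindowFst:
    def test_window_of_fixed_differences_is_one(self):
        sites = make_sites([("c", i, 50.0, 0, 20, 20, 0) for i in range(1, 6)])
        assert window_fst(sites, haploids_a=10**6, haploids_b=10**6) == pytest.approx(
            1.0, abs=1e-5
        )

    def test_identical_groups_nonpositive(self):
        sites = make_sites([("c", i, 50.0, 15, 5, 15, 5) for i in range(1, 6)])
        assert window_fst(sites, haploids_a=20, haploids_b=20) <= 0

    def test_ratio_of_sums_not_mean_of_ratios(self):
        sites = make_sites([
            ("c", 1, 50.0, 2, 8, 8, 2),
            ("c", 2, 50.0, 10, 10, 10, 10),
        ])
        num, den = snp_fst(sites["a_major"], sites["a_minor"],
                           sites["b_major"], sites["b_minor"],
                           haploids_a=20, haploids_b=20)
        expect = num.sum() / den.sum()
        assert window_fst(sites, haploids_a=20, haploids_b=20) == pytest.approx(
            expect, rel=1e-12
        )
        assert expect != pytest.approx(np.mean(num / den), rel=1e-3)


class TestMakeWindows:
    @pytest.mark.parametrize("length,expected", [
        (100_000, 6), (49_999, 0), (50_000, 1), (50_001, 1),
        (59_999, 1), (60_000, 2), (1_000_000, 96),
    ])
    def test_count_matches_closed_form(self, length, expected):
        win = make_windows([ContigSpec("c", length)], 50_000, 10_000)
        assert len(win) == expected
        if expected:
            assert win.iloc[0]["start"] == 1 and win.iloc[0]["end"] == 50_000
            assert (win["end"] <= length).all()

    def test_multiple_contigs_independent(self):
        win = make_windows(
            [ContigSpec("a", 100_000), ContigSpec("b", 30_000)], 50_000, 10_000
        )
        assert list(win["contig"].unique()) == ["a"]


class TestZTransform:
    def test_two_values(self):
        z = z_transform([0.0, 2.0])
        assert z == pytest.approx([-1 / math.sqrt(2), 1 / math.sqrt(2)])

    def test_output_standardised(self):
        rng = np.random.default_rng(0)
        z = z_transform(rng.normal(3.0, 2.0, 500))
        assert abs(z.mean()) < 1e-9
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("bad", [[1.0], [2.0, 2.0, 2.0], [1.0, np.nan]])
    def test_degenerate_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            z_transform(bad)


def _window_oracle(sites, frame, config):
    """Recompute one window from scratch (independent of the prefix-sum path)."""
    inside = sites[
        (sites["contig"] == frame.contig)
        & (sites["pos"] >= frame.start)
        & (sites["pos"] <= frame.end)
    ]
    if len(inside) == 0:
        return None
    hp_a = pooled_heterozygosity(inside, "A")
    hp_b = pooled_heterozygosity(inside, "B")
    fst = window_fst(inside, config.fst_estimator,
                     config.haploids_a, config.haploids_b)
    return len(inside), hp_a, hp_b, fst


class TestScan:
    def test_matches_naive_per_window_oracle(self, random_sites):
        config = ScanConfig(window_size=50_000, step=10_000, min_sites=1)
        win = scan(random_sites, config, contigs=[ContigSpec("chr1", 500_000)])
        assert len(win) == 46
        for frame in win.itertuples(index=False):
            oracle = _window_oracle(random_sites, frame, config)
            assert oracle is not None
            n, hp_a, hp_b, fst = oracle
            assert frame.n_sites == n
            assert frame.hp_a == hp_a and frame.hp_b == hp_b
            assert frame.fst == pytest.approx(fst, rel=1e-12)

    def test_sparse_window_discarded_without_z(self):
        rows = [("c", p, 50.0, 20, 5, 10, 10) for p in range(1, 50_000, 6000)]
        sites = make_sites(rows)  # 9 sites in the first window
        win = scan(sites, ScanConfig(min_sites=10),
                   contigs=[ContigSpec("c", 120_000)])
        first = win.iloc[0]
        assert first["n_sites"] == 9 and bool(first["discarded"])
        assert math.isnan(first["z_fst"])

    def test_complete_sweep_hits_hp_floor(self):
        rows = [("c", p, 50.0, 30, 0, 15, 15) for p in range(1, 50_001, 1000)]
        win = scan(make_sites(rows), ScanConfig(min_sites=10),
                   contigs=[ContigSpec("c", 50_000)])
        first = win.iloc[0]
        assert first["hp_a"] == 0.0
        assert first["ln_hp_ratio"] == pytest.approx(math.log(0.5 / 1e-4))

    def test_identical_groups_have_zero_ln_ratio(self, random_sites):
        sym = random_sites.copy()
        sym[["b_major", "b_minor"]] = sym[["a_major", "a_minor"]].to_numpy()
        win = scan(sym, ScanConfig(min_sites=1), contigs=[ContigSpec("chr1", 500_000)])
        assert (win["ln_hp_ratio"] == 0.0).all()

    def test_group_swap_negates_ln_ratio_and_preserves_fst(self, random_sites):
        config = ScanConfig(min_sites=1, haploids_a=800, haploids_b=400)
        swapped_config = ScanConfig(min_sites=1, haploids_a=400, haploids_b=800)
        swapped = random_sites.rename(columns={
            "a_major": "b_major", "a_minor": "b_minor",
            "b_major": "a_major", "b_minor": "a_minor",
        })
        win = scan(random_sites, config, contigs=[ContigSpec("chr1", 500_000)])
        win_s = scan(swapped, swapped_config, contigs=[ContigSpec("chr1", 500_000)])
        np.testing.assert_array_equal(
            win_s["ln_hp_ratio"].to_numpy(), -win["ln_hp_ratio"].to_numpy()
        )
        np.testing.assert_array_equal(win_s["fst"].to_numpy(), win["fst"].to_numpy())


class TestExtractOutliers:
    def test_intersection_rule_and_strict_cutoff(self):
        win = pd.DataFrame({
            "contig": "c", "start": [1, 2, 3, 4], "end": [10, 20, 30, 40],
            "n_sites": 20, "discarded": False,
            "z_fst": [41.19, 6.0, 5.0, 7.0],
            "z_hp_ratio": [11.82, 4.9, 7.0, 5.0],
        })
        out = extract_outliers(win, 5.0)
        assert list(out["start"]) == [1]  # 6.0/4.9 fails intersection,
        # 5.0 exactly fails the strict inequality on either axis

    def test_discarded_windows_never_outliers(self):
        win = pd.DataFrame({
            "contig": "c", "start": [1], "end": [10], "n_sites": 3,
            "discarded": True, "z_fst": [9.0], "z_hp_ratio": [9.0],
        })
        assert len(extract_outliers(win, 5.0)) == 0
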