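"""Unit tests of the 345-statistic featurizer against naive oracles and
hand-computed examples."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from demosel.features import (
    SubregionLayout,
    bet_distribution,
    feature_blocks,
    feature_names,
    featurize,
    folded_sfs,
    h_statistics,
    ibs_distribution,
    ld_distribution,
    seg_sites_stat,
    tajimas_d,
    _ibs_accumulate,
    IBS_EDGES,
)
from demosel.simdata import HaplotypeRegion

from tests import oracles

SUBS = ("close", "mid", "far")


def make_region(rng, n, S, L=1000):
    return oracles.random_region(rng, n, S, L)


@pytest.mark.parametrize("n", [2, 3, 4, 6])
@pytest.mark.parametrize("S", [0, 1, 2, 5, 8])
def test_statistics_match_naive_oracles(n, S):
    """Every per-subregion statistic equals a from-definition loop
    implementation on small random matrices."""
    layout = SubregionLayout(1000)
    for seed in range(4):
        rng = np.random.default_rng(1000 * n + 10 * S + seed)
        region = make_region(rng, n, S)
        for sub in SUBS:
            intervals = layout.intervals(sub)
            cols = [j for j, p in enumerate(region.positions)
                    if any(a <= p < b for a, b in intervals)]
            sub_mat = region.alleles[:, cols]
            sub_pos = [region.positions[j] for j in cols]

            assert seg_sites_stat(region, sub) == pytest.approx(
                min(len(cols), 5000) / 5000)
            assert tajimas_d(region, sub, raw=True) == pytest.approx(
                oracles.tajimas_d_raw(sub_mat), abs=1e-10)
            np.testing.assert_allclose(
                folded_sfs(region, sub, n_bins=n // 2),
                oracles.folded_sfs(sub_mat, n // 2), atol=1e-12)
            np.testing.assert_allclose(
                bet_distribution(region, sub),
                oracles.bet_histogram(sub_pos, len(cols), intervals),
                atol=1e-12)
            np.testing.assert_allclose(
                ibs_distribution(region, sub),
                oracles.ibs_histogram(region.alleles, region.positions,
                                      intervals), atol=1e-12)
            np.testing.assert_allclose(
                ld_distribution(region, sub),
                oracles.ld_histogram(region.alleles, region.positions,
                                     layout.intervals("close"), intervals,
                                     sub == "close"), atol=1e-12)
        np.testing.assert_allclose(
            h_statistics(region),
            oracles.h_stats(region.alleles[:, [
                j for j, p in enumerate(region.positions) if 400 <= p < 600]]),
            atol=1e-12)


def test_statistics_match_oracles_exhaustive_tiny():
    """All 2x2 binary matrices with segregating columns, enumerated."""
    layout = SubregionLayout(1000)
    positions = np.array([450, 550])
    for c0 in ((0, 1), (1, 0)):
        for c1 in ((0, 1), (1, 0)):
            mat = np.array([[c0[0], c1[0]], [c0[1], c1[1]]], dtype=np.uint8)
            region = HaplotypeRegion(mat, positions, 1000)
            assert tajimas_d(region, "close", raw=True) == pytest.approx(
                oracles.tajimas_d_raw(mat), abs=1e-10)
            np.testing.assert_allclose(
                ibs_distribution(region, "close"),
                oracles.ibs_histogram(mat, positions,
                                      layout.intervals("close")))
            np.testing.assert_allclose(h_statistics(region),
                                       oracles.h_stats(mat))


class TestSegSites:
    def test_empty_is_zero(self):
        region = HaplotypeRegion(np.zeros((4, 0), np.uint8),
                                 np.zeros(0, np.int64), 100_000)
        assert seg_sites_stat(region, "close") == 0.0

    @pytest.mark.parametrize("S,expected", [(2500, 0.5), (5000, 1.0),
                                            (7000, 1.0)])
    def test_truncation_at_5000(self, S, expected):
        """S_max = 5000; larger counts are truncated."""
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(40_000, 60_000), S, replace=False))
        mat = np.zeros((2, S), np.uint8)
        mat[0] = 1
        region = HaplotypeRegion(mat, pos, 100_000)
        assert seg_sites_stat(region, "close") == pytest.approx(expected)


class TestTajimasD:
    def test_no_variation_convention(self):
        region = HaplotypeRegion(np.zeros((4, 0), np.uint8),
                                 np.zeros(0, np.int64), 1000)
        assert tajimas_d(region, "close", raw=True) == 0.0
        assert tajimas_d(region, "close") == 0.5

    def test_normalization_maps_pm3_to_unit_interval(self):
        rng = np.random.default_rng(5)
        region = make_region(rng, 6, 8)
        for sub in SUBS:
            raw = tajimas_d(region, sub, raw=True)
            norm = tajimas_d(region, sub)
            assert norm == pytest.approx(
                min(max((raw + 3) / 6, 0.0), 1.0))


class TestFoldedSFS:
    def test_hand_counts_n4(self):
        """Minor-allele counts {1,1,2} at n=4 -> (2/3, 1/3)."""
        mat = np.array([[1, 0, 1],
                        [0, 1, 1],
                        [0, 0, 0],
                        [0, 0, 0]], dtype=np.uint8)
        region = HaplotypeRegion(mat, np.array([450, 500, 550]), 1000)
        np.testing.assert_allclose(folded_sfs(region, "close", n_bins=2),
                                   [2 / 3, 1 / 3])

    def test_zero_when_no_sites(self):
        region = HaplotypeRegion(np.zeros((4, 0), np.uint8),
                                 np.zeros(0, np.int64), 1000)
        assert folded_sfs(region, "close", n_bins=2).sum() == 0.0


class TestBet:
    def test_hand_gaps(self):
        """Positions (100, 110, 499) in one interval: gaps 10 and 389 ->
        first and last bin, each with weight 1/S = 1/3."""
        mat = np.array([[1, 1, 1], [0, 0, 0]], dtype=np.uint8)
        region = HaplotypeRegion(mat, np.array([100, 110, 499]), 2500)
        # far subregion of L=2500 is [0,500) u [2000,2500): all three sites
        out = bet_distribution(region, "far")
        assert out[0] == pytest.approx(1 / 3)
        assert out[15] == pytest.approx(1 / 3)
        assert out.sum() == pytest.approx(2 / 3)

    def test_single_site_all_zero(self):
        mat = np.array([[1], [0]], dtype=np.uint8)
        region = HaplotypeRegion(mat, np.array([450]), 1000)
        assert bet_distribution(region, "close").sum() == 0.0


class TestIbs:
    def test_identical_pair_full_length_tract(self):
        """Two identical haplotypes: one tract spanning the whole
        subregion interval, in the open-ended last bin."""
        mat = np.zeros((2, 1), np.uint8)
        mat[0, 0] = 1
        region = HaplotypeRegion(mat, np.array([10]), 100_000)
        out = ibs_distribution(region, "close")  # no sites in close
        assert out[-1] == pytest.approx(1.0)

    def test_boundary_delimited_tracts(self):
        """Mismatch at bp 5 inside [0,10): tracts of length 5 and 4."""
        counts = np.zeros(30)
        total = _ibs_accumulate(np.array([5]), np.array([0]), 1, 0, 10,
                                counts)
        assert total == 2
        assert counts[0] == 2  # both lengths < 5000/29

    def test_histogram_sums_to_one(self):
        rng = np.random.default_rng(8)
        region = make_region(rng, 5, 6)
        for sub in SUBS:
            assert ibs_distribution(region, sub).sum() == pytest.approx(1.0)


class TestLd:
    def test_perfectly_linked_pair_last_bin(self):
        """p_A = p_B = 0.5 with p_AB = 0.5 gives D_AB = 0.25 -> last bin."""
        mat = np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.uint8)
        region = HaplotypeRegion(mat, np.array([450, 550]), 1000)
        out = ld_distribution(region, "close")
        assert out[-1] == pytest.approx(1.0)

    def test_independent_sites_zero_d(self):
        """p_AB = p_A * p_B puts the pair in the bin containing 0."""
        mat = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.uint8)
        region = HaplotypeRegion(mat, np.array([450, 550]), 1000)
        out = ld_distribution(region, "close")
        # D = 0.25 - 0.25 = 0 -> interior bin [0.0326..., ...) no: bin of 0
        k = np.flatnonzero(out)[0]
        width = 0.25 / 14
        lo = -0.05 + (k - 1) * width
        assert lo <= 0 < lo + width

    def test_no_pairs_all_zero(self):
        region = HaplotypeRegion(np.zeros((4, 0), np.uint8),
                                 np.zeros(0, np.int64), 1000)
        for sub in SUBS:
            assert ld_distribution(region, sub).sum() == 0.0


class TestHStatistics:
    def test_single_class(self):
        region = HaplotypeRegion(np.zeros((5, 0), np.uint8),
                                 np.zeros(0, np.int64), 1000)
        assert h_statistics(region) == (1.0, 1.0, 0.0)

    def test_two_equal_classes(self):
        mat = np.array([[1], [1], [0], [0]], dtype=np.uint8)
        region = HaplotypeRegion(mat, np.array([500]), 1000)
        h1, h12, h2 = h_statistics(region)
        assert (h1, h12, h2) == pytest.approx((0.5, 1.0, 0.25))

    def test_three_classes_05_03_02(self):
        """Frequencies 0.5/0.3/0.2 -> H1=0.38, H12=0.68, H2=0.13."""
        rows = [[0, 0]] * 5 + [[1, 0]] * 3 + [[1, 1]] * 2
        region = HaplotypeRegion(np.array(rows, np.uint8),
                                 np.array([450, 550]), 1000)
        h1, h12, h2 = h_statistics(region)
        assert (h1, h12, h2) == pytest.approx((0.38, 0.68, 0.13))


class TestFeaturize:
    def test_length_and_blocks(self):
        rng = np.random.default_rng(1)
        region = make_region(rng, 100, 40, L=100_000)
        vec = featurize(region)
        assert vec.shape == (345,)
        assert np.all((vec >= 0) & (vec <= 1))
        blocks = feature_blocks()
        assert len(feature_names()) == 345
        assert {k: len(v) for k, v in blocks.items()} == {
            "S": 3, "D": 3, "SFS": 150, "BET": 48, "IBS": 90, "LD": 48,
            "H": 3}

    def test_wrong_n_raises(self):
        rng = np.random.default_rng(2)
        region = make_region(rng, 10, 5)
        with pytest.raises(Exception, match="n=10"):
            featurize(region)

    def test_empty_region_conventions(self):
        """S=0: S-stats 0, D-stats 0.5, SFS/BET/LD zero, H=(1,1,0);
        identical haplotypes give full-length IBS tracts (last bin)."""
        region = HaplotypeRegion(np.zeros((100, 0), np.uint8),
                                 np.zeros(0, np.int64), 100_000)
        vec = featurize(region)
        names = feature_names()
        by = dict(zip(names, vec))
        for sub in SUBS:
            assert by[f"S_{sub}"] == 0.0
            assert by[f"D_{sub}"] == 0.5
            assert sum(by[f"SFS_{sub}_{i}"] for i in range(1, 51)) == 0.0
            assert sum(by[f"BET_{sub}_{j}"] for j in range(1, 17)) == 0.0
            assert sum(by[f"LD_{sub}_{j}"] for j in range(1, 17)) == 0.0
            assert by[f"IBS_{sub}_30"] == 1.0
        assert (by["H1"], by["H12"], by["H2"]) == (1.0, 1.0, 0.0)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_row_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        region = make_region(rng, 5, int(rng.integers(0, 9)))
        perm = rng.permutation(region.n)
        permuted = HaplotypeRegion(region.alleles[perm], region.positions,
                                   region.region_len)
        a = featurize(region, expected_n=5)
        b = featurize(permuted, expected_n=5)
        np.testing.assert_allclose(a, b, atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_end_for_end_flip_invariance(self, seed):
        """Reversing the region maps far/mid intervals onto themselves, so
        the whole feature vector is unchanged."""
        rng = np.random.default_rng(seed)
        region = make_region(rng, 4, int(rng.integers(0, 9)))
        L = region.region_len
        flipped = HaplotypeRegion(region.alleles[:, ::-1],
                                  (L - 1 - region.positions)[::-1], L)
        np.testing.assert_allclose(featurize(region, expected_n=4),
                                   featurize(flipped, expected_n=4),
                                   atol=1e-12)

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 10_000))
    def test_distribution_block_sums(self, seed):
        """SFS/IBS/LD blocks sum to 1 or 0; BET sums to at most 1 (the
        count of gaps over the count of sites)."""
        rng = np.random.default_rng(seed)
        region = make_region(rng, 6, int(rng.integers(0, 9)))
        vec = featurize(region, expected_n=6)
        names = feature_names(6)
        by = dict(zip(names, vec))
        for sub in SUBS:
            for fam, k in (("SFS", 3), ("IBS", 30), ("LD", 16)):
                s = sum(by[f"{fam}_{sub}_{i}"] for i in range(1, k + 1))
                assert s == pytest.approx(1.0) or s == 0.0
            bet = sum(by[f"BET_{sub}_{j}"] for j in range(1, 17))
            assert 0.0 <= bet < 1.0 + 1e-12
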