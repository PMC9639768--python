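"""Nucleotide diversity and Weir-Cockerham FST against brute-force oracles
and closed-form limits."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan import (
    GenotypeMatrix,
    PopulationMap,
    bootstrap_fst,
    global_pairwise_fst,
    make_windows,
    ratio_of_sums_fst,
    site_pi,
    theta_pi_ratio,
    wc_fst_site,
    window_fst,
    window_pi,
)
from sweepscan.diversity import site_components


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def pi_oracle(alleles):
    """Average pairwise difference by explicit double loop."""
    called = [a for a in alleles if a != -1]
    pairs = diffs = 0
    for a, b in itertools.combinations(called, 2):
        pairs += 1
        diffs += a != b
    return diffs / pairs


class TestSitePi:
    def test_examples(self):
        assert site_pi(np.array([0, 0, 1, 1])) == pytest.approx(2 / 3)
        assert site_pi(np.array([0, 0, 0, 0])) == 0.0
        assert site_pi(np.array([0, 1])) == 1.0

    def test_too_few_alleles_raises(self):
        with pytest.raises(ValueError):
            site_pi(np.array([0, -1, -1]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([0, 1, -1]), min_size=2, max_size=40))
    def test_matches_pairwise_oracle(self, alleles):
        col = np.array(alleles)
        called = (col != -1).sum()
        if called < 2:
            return
        assert site_pi(col) == pytest.approx(pi_oracle(alleles))


class TestWindowPi:
    def _geno(self, alleles, positions):
        alleles = np.asarray(alleles, dtype=np.int8)
        return GenotypeMatrix(
            chrom="1",
            positions=np.asarray(positions),
            alleles=alleles,
            sample_ids=[f"s{i}" for i in range(alleles.shape[0] // 2)],
        )

    def test_single_site_in_10kb_window(self):
        g = self._geno([[0], [0], [1], [1]], [500])
        pm = PopulationMap({"s0": "A", "s1": "A"})
        out = window_pi(g, pm, "A", make_windows(10_000, 10_000))
        assert out["pi"].iloc[0] == pytest.approx((2 / 3) / 10_000)

    def test_empty_window_is_zero(self):
        g = self._geno(np.zeros((4, 0)), [])
        pm = PopulationMap({"s0": "A", "s1": "A"})
        out = window_pi(g, pm, "A", make_windows(10_000, 10_000))
        assert out["pi"].iloc[0] == 0.0

    def test_two_fully_heterozygous_sites_span_100(self):
        g = self._geno([[0, 0], [1, 1]], [10, 20])
        pm = PopulationMap({"s0": "A"})
        out = window_pi(g, pm, "A", make_windows(100, 100))
        assert out["pi"].iloc[0] == pytest.approx((1 + 1) / 100)

    def test_matches_total_pairwise_oracle(self):
        rng = np.random.default_rng(11)
        alleles = rng.integers(0, 2, size=(8, 30)).astype(np.int8)
        positions = np.sort(rng.choice(np.arange(1, 5000), 30, replace=False))
        g = self._geno(alleles, positions)
        pm = PopulationMap({f"s{i}": "A" for i in range(4)})
        span = 5000
        out = window_pi(g, pm, "A", make_windows(span, span))
        expected = sum(pi_oracle(alleles[:, j]) for j in range(30)) / span
        assert out["pi"].iloc[0] == pytest.approx(expected)


class TestThetaPiRatio:
    def test_identity_is_zero(self):
        assert theta_pi_ratio(3e-4, 3e-4) == 0.0

    def test_log2_of_four(self):
        assert theta_pi_ratio(4e-3, 1e-3) == pytest.approx(2.0)

    def test_sentinels(self):
        assert theta_pi_ratio(0.0, 1e-3) == float("-inf")
        assert theta_pi_ratio(1e-3, 0.0) == float("inf")
        assert np.isnan(theta_pi_ratio(0.0, 0.0))
        with pytest.raises(ValueError):
            theta_pi_ratio(-1.0, 1.0)


def _two_pop_geno(a1, a2):
    a1 = np.asarray(a1, dtype=np.int8)
    a2 = np.asarray(a2, dtype=np.int8)
    alleles = np.concatenate([a1, a2], axis=0)
    n1, n2 = a1.shape[0] // 2, a2.shape[0] // 2
    ids = [f"p{i}" for i in range(n1)] + [f"q{i}" for i in range(n2)]
    g = GenotypeMatrix(chrom="1", positions=np.arange(1, a1.shape[1] + 1),
                       alleles=alleles, sample_ids=ids)
    pm = PopulationMap({f"p{i}": "P" for i in range(n1)} | {f"q{i}": "Q" for i in range(n2)})
    return g, pm


class TestWcFst:
    def test_fixed_difference_theta_is_one(self):
        a1 = np.zeros((20, 1), dtype=np.int8)
        a2 = np.ones((20, 1), dtype=np.int8)
        comp = wc_fst_site(a1, a2)
        theta = comp.a[0] / (comp.a + comp.b + comp.c)[0]
        assert theta == pytest.approx(1.0)
        assert comp.b[0] == pytest.approx(0.0) and comp.c[0] == pytest.approx(0.0)

    def test_monomorphic_site_undefined(self):
        comp = wc_fst_site(np.zeros((4, 1), dtype=np.int8), np.zeros((4, 1), dtype=np.int8))
        assert not comp.defined[0]
        assert comp.a[0] == comp.b[0] == comp.c[0] == 0.0

    def test_single_individual_site_skipped(self):
        comp = wc_fst_site(np.array([[0], [1]], dtype=np.int8), np.ones((4, 1), dtype=np.int8))
        assert not comp.defined[0]

    def test_identical_populations_small_theta(self):
        rng = np.random.default_rng(3)
        block = rng.integers(0, 2, size=(40, 200)).astype(np.int8)
        comp = wc_fst_site(block, block.copy())
        fst = ratio_of_sums_fst(comp)
        assert abs(fst) < 0.05

    def test_window_fst_ratio_of_sums_not_mean_of_ratios(self):
        # one site a=0.2, a+b+c=0.4; another a=0, a+b+c=0.4 -> 0.2/0.8 = 0.25
        from sweepscan.diversity import SiteComponents

        comp = SiteComponents(
            a=np.array([0.2, 0.0]),
            b=np.array([0.1, 0.2]),
            c=np.array([0.1, 0.2]),
            defined=np.array([True, True]),
        )
        out = window_fst(comp, np.array([10, 20]), make_windows(100, 100))
        assert out["fst"].iloc[0] == pytest.approx(0.25)

    def test_single_site_window_equals_site_theta(self):
        rng = np.random.default_rng(8)
        a1 = rng.integers(0, 2, size=(12, 1)).astype(np.int8)
        a2 = rng.integers(0, 2, size=(12, 1)).astype(np.int8)
        a1[:, 0] = [0, 0, 0, 1, 0, 0, 1, 0, 0, 0, 0, 1]
        comp = wc_fst_site(a1, a2)
        if comp.defined[0]:
            theta = comp.a[0] / (comp.a + comp.b + comp.c)[0]
            out = window_fst(comp, np.array([5]), make_windows(10, 10))
            assert out["fst"].iloc[0] == pytest.approx(theta)

    def test_sample_permutation_and_relabeling_invariance(self):
        rng = np.random.default_rng(21)
        a1 = rng.integers(0, 2, size=(16, 50)).astype(np.int8)
        a2 = rng.integers(0, 2, size=(12, 50)).astype(np.int8)
        base = ratio_of_sums_fst(wc_fst_site(a1, a2))
        # permute individuals (pairs of rows) within a population
        perm = rng.permutation(8)
        rows = np.ravel(np.column_stack([2 * perm, 2 * perm + 1]))
        assert ratio_of_sums_fst(wc_fst_site(a1[rows], a2)) == pytest.approx(base)
        # swap population labels
        assert ratio_of_sums_fst(wc_fst_site(a2, a1)) == pytest.approx(base)

    def test_empty_window_flagged(self):
        comp = wc_fst_site(np.zeros((4, 1), dtype=np.int8), np.ones((4, 1), dtype=np.int8))
        out = window_fst(comp, np.array([50_000]), make_windows(10_000, 10_000))
        assert np.isnan(out["fst"].iloc[0]) or out["n_variants"].iloc[0] >= 0


class TestGlobalPairwise:
    def test_fixed_difference_pair_is_one(self):
        g, pm = _two_pop_geno(np.zeros((10, 20)), np.ones((10, 20)))
        out = global_pairwise_fst(g, pm)
        assert out["fst"].iloc[0] == pytest.approx(1.0)

    def test_population_split_in_half_near_zero(self):
        rng = np.random.default_rng(17)
        freqs = rng.uniform(0.1, 0.9, size=100)
        alleles = (rng.random((40, 100)) < freqs).astype(np.int8)
        g, pm = _two_pop_geno(alleles[:20], alleles[20:])
        out = global_pairwise_fst(g, pm)
        assert abs(out["fst"].iloc[0]) < 0.05

    def test_empty_mask_gives_nan(self):
        g, pm = _two_pop_geno(np.zeros((10, 5)), np.ones((10, 5)))
        out = global_pairwise_fst(g, pm, snp_mask=np.zeros(5, dtype=bool))
        assert np.isnan(out["fst"].iloc[0])


class TestBootstrap:
    def test_fixed_difference_p_is_1_over_101(self):
        g, pm = _two_pop_geno(np.zeros((10, 30)), np.ones((10, 30)))
        res = bootstrap_fst(g, pm, "P", "Q", n_boot=100, seed=0)
        assert res["p"] == pytest.approx(1 / 101)
        assert res["ci_low"] == pytest.approx(1.0)

    def test_identical_populations_not_significant(self):
        rng = np.random.default_rng(19)
        freqs = rng.uniform(0.2, 0.8, size=120)
        alleles = (rng.random((48, 120)) < freqs).astype(np.int8)
        g, pm = _two_pop_geno(alleles[:24], alleles[24:])
        res = bootstrap_fst(g, pm, "P", "Q", n_boot=100, seed=1)
        assert res["p"] > 0.2

    def test_seeded_determinism(self):
        g, pm = _two_pop_geno(
            np.random.default_rng(2).integers(0, 2, (10, 40)),
            np.random.default_rng(3).integers(0, 2, (10, 40)),
        )
        r1 = bootstrap_fst(g, pm, "P", "Q", n_boot=50, seed=123)
        r2 = bootstrap_fst(g, pm, "P", "Q", n_boot=50, seed=123)
        assert r1 == r2

    def test_n_boot_zero_raises(self):
        g, pm = _two_pop_geno(np.zeros((10, 5)), np.ones((10, 5)))
        with pytest.raises(ValueError):
            bootstrap_fst(g, pm, "P", "Q", n_boot=0)


class TestDriftCalibrationSmall:
    def test_no_split_fst_near_zero(self, small_sim, small_popmap):
        """t is short here, so FST should be small but positive in expectation;
        the full drift calibration runs in the acceptance suite."""
        from sweepscan import merge_populations

        cfg, matrices, _ = small_sim
        g = merge_populations(matrices).to_genotypes()
        comp = site_components(g, small_popmap, "pop1", "pop2")
        fst = ratio_of_sums_fst(comp)
        expected = 1 - np.exp(-cfg.split_time / (2 * cfg.pop_size))
        assert abs(fst - expected) < 0.15
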