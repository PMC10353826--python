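"""Diversity / differentiation statistics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selfingpop.diversity import (
    exclude_intervals,
    fold_sfs,
    ld_decay,
    pi_window,
    polarize,
    sfs,
    tajima_constants,
    tajimas_d,
    tajimas_d_window,
    wc_fst_global,
    wc_fst_window,
)
from selfingpop.genotype import MISSING, MaskSet
from tests.conftest import make_matrix


class TestPolarize:
    def test_outgroup_matches_ref_unchanged(self):
        g = make_matrix([[0, 1], [1, 0]])
        g2, dropped = polarize(g, np.array([0, 0]))
        assert dropped == 0
        np.testing.assert_array_equal(g2.calls, g.calls)

    def test_outgroup_alt_flips_column(self):
        g = make_matrix([[0, 1], [1, 1], [1, 0]])
        g2, _ = polarize(g, np.array([1, 0]))
        np.testing.assert_array_equal(g2.calls[:, 0], [1, 0, 0])
        assert g2.ref_allele[0] == "T" and g2.alt_allele[0] == "A"

    def test_unpolarizable_site_dropped(self):
        g = make_matrix([[0, 1, 0], [1, 0, 1]])
        g2, dropped = polarize(g, np.array([0, MISSING, 1]))
        assert dropped == 1 and g2.n_sites == 2


class TestSfs:
    def test_direct_count(self):
        # 4 haplotypes, derived counts (1, 1, 2, 3)
        calls = np.array(
            [[1, 0, 1, 1], [0, 1, 1, 1], [0, 0, 0, 1], [0, 0, 0, 0]], dtype=np.int8
        )  # 4 samples x 4 sites, column sums 1, 1, 2, 3
        g = make_matrix(calls)
        counts = (g.calls == 1).sum(axis=0)
        assert sorted(counts) == [1, 1, 2, 3]
        spec = sfs(g)
        np.testing.assert_array_equal(spec.counts, [0, 2, 1, 1, 0])

    def test_invariant_padding(self):
        g = make_matrix(np.zeros((4, 0), dtype=np.int8), pos=[])
        spec = sfs(g, include_invariant=True, total_callable=100)
        assert spec.counts[0] == 100 and spec.counts.sum() == 100

    def test_folding(self):
        from selfingpop.diversity import SiteFrequencySpectrum

        spec = SiteFrequencySpectrum(n=4, counts=[0, 2, 1, 1, 0])
        folded = fold_sfs(spec)
        np.testing.assert_array_equal(folded.counts, [0, 3, 1])

    def test_missing_sites_dropped(self):
        calls = np.array([[1, MISSING], [0, 1], [0, 1], [0, 1]], dtype=np.int8)
        spec = sfs(make_matrix(calls))
        assert spec.counts.sum() == 1


class TestPiWindow:
    def test_single_snp_formula(self):
        # one SNP, derived count 2 of n=4, callable denominator 1000
        calls = np.array([[1], [1], [0], [0]], dtype=np.int8)
        g = make_matrix(calls, pos=[500])
        ws = pi_window(g, span=1000, stride=1000, chrom_lengths={"chr1": 1000})
        assert len(ws) == 1
        assert ws[0].value == pytest.approx((2 * 2 * 2 / 12) / 1000)
        assert ws[0].value == pytest.approx(6.667e-4, rel=1e-3)

    def test_monomorphic_window_zero(self):
        g = make_matrix(np.zeros((4, 3), dtype=np.int8))
        ws = pi_window(g, span=100, stride=100)
        assert all(w.value == 0 for w in ws)

    def test_masked_aware_denominator(self):
        calls = np.array([[1], [0]], dtype=np.int8)
        g = make_matrix(calls, pos=[10])
        ms = MaskSet()
        for s in g.sample_ids:
            ms._iv.setdefault(s, {})
        ms.add("s00", "chr1", 51, 100)
        ws = pi_window(g, masks=ms, span=100, stride=100, chrom_lengths={"chr1": 100})
        # 50 positions masked for s00 -> callable = 50
        assert ws[0].callable_sites == 50


def _tajimas_d_oracle(calls):
    """Independent implementation straight from the 1989 definitions."""
    n, m = calls.shape
    c = calls.sum(axis=0)
    seg = (c > 0) & (c < n)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    # mean pairwise differences, computed pair by pair
    k = 0.0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            k += (calls[i] != calls[j]).sum()
            npairs += 1
    k /= npairs
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        assert np.isnan(tajimas_d(0.0, 0, 10))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 4 + int(seed % 7), 30
        calls = (rng.random((n, m)) < 0.3).astype(np.int8)
        g = make_matrix(calls)
        ws = tajimas_d_window(g, span=10_000, stride=10_000)
        expected = _tajimas_d_oracle(calls)
        if np.isnan(expected):
            assert np.isnan(ws[0].value)
        else:
            assert ws[0].value == pytest.approx(expected, abs=1e-9)

    def test_constants_sanity(self):
        k = tajima_constants(10)
        assert k["a1"] == pytest.approx(sum(1 / i for i in range(1, 10)))
        assert k["e1"] > 0 and k["e2"] > 0

    def test_invariant_to_polarization_flip(self):
        rng = np.random.default_rng(3)
        calls = (rng.random((6, 40)) < 0.4).astype(np.int8)
        g = make_matrix(calls)
        d1 = tajimas_d_window(g, span=10_000, stride=10_000)[0].value
        g2, _ = polarize(g, np.ones(40, dtype=int))
        d2 = tajimas_d_window(g2, span=10_000, stride=10_000)[0].value
        assert d1 == pytest.approx(d2, abs=1e-12)


class TestWcFst:
    def _labels(self, g, half):
        return {
            s: ("p1" if i < half else "p2") for i, s in enumerate(g.sample_ids)
        }

    def test_fixed_differences_give_one(self):
        calls = np.vstack([np.zeros((5, 10)), np.ones((5, 10))]).astype(np.int8)
        g = make_matrix(calls)
        assert wc_fst_global(g, self._labels(g, 5)) == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.2, 0.8, 400)
        calls = (rng.random((50, 400)) < p).astype(np.int8)
        g = make_matrix(calls)
        est = wc_fst_global(g, self._labels(g, 25))
        assert abs(est) <= 0.02

    def test_window_floor_drops_sparse_windows(self):
        rng = np.random.default_rng(1)
        calls = (rng.random((8, 20)) < 0.5).astype(np.int8)
        g = make_matrix(calls)
        ws = wc_fst_window(g, self._labels(g, 4), span=1000, stride=1000, min_snps=700)
        assert ws == []


class TestLdDecay:
    def test_duplicated_column_counts_r2_one(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 2, 30).astype(np.int8)
        calls = np.column_stack([col, col])
        g = make_matrix(calls, pos=[100, 1100])
        bins = ld_decay(g, max_dist=5000, bin_width=1000)
        assert bins[1].n_pairs == 1 and bins[1].mean_r2 == pytest.approx(1.0)

    def test_independent_sites_flat_near_bias_floor(self):
        rng = np.random.default_rng(2)
        n = 40
        calls = (rng.random((n, 200)) < 0.5).astype(np.int8)
        g = make_matrix(calls, pos=np.arange(1, 201) * 500)
        bins = ld_decay(g, max_dist=20_000, bin_width=10_000)
        for b in bins:
            if b.n_pairs > 100:
                assert b.mean_r2 == pytest.approx(1 / n, abs=3 / n)


def test_exclude_intervals():
    g = make_matrix(np.zeros((2, 5), dtype=np.int8), pos=[10, 20, 30, 40, 50])
    g2 = exclude_intervals(g, [("chr1", 15, 35)])
    np.testing.assert_array_equal(g2.pos, [10, 40, 50])
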