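"""Masked pairwise distances, MDS, clustering and mode detection."""

import itertools

import numpy as np
import pytest

from selfingpop.distances import (
    DistanceMatrix,
    classical_mds,
    hierarchical_cluster,
    masked_pgd,
    pgd_mode_detection,
    relatedness_filter,
)
from selfingpop.genotype import MISSING, MaskSet
from tests.conftest import make_matrix


class TestMaskedPgd:
    def test_identical_strains_distance_zero(self):
        g = make_matrix([[0, 1, 0], [0, 1, 0]])
        d = masked_pgd(g)
        assert d.dist[0, 1] == 0.0

    def test_one_difference_over_thousand_positions(self):
        g = make_matrix([[0, 0], [0, 1]], pos=[10, 20])
        ms = MaskSet()
        ms._iv.setdefault("s00", {})
        ms._iv.setdefault("s01", {})
        d = masked_pgd(g, masks=ms, chrom_lengths={"chr1": 1000})
        assert d.dist[0, 1] == pytest.approx(0.001)
        assert d.n_observed[0, 1] == 1000

    def test_masked_site_excluded_matches_enumeration(self):
        # 10-site toy: brute-force every pair by walking the genome
        rng = np.random.default_rng(0)
        n, m, L = 3, 10, 200
        pos = np.sort(rng.choice(np.arange(1, L + 1), m, replace=False))
        calls = rng.integers(0, 2, size=(n, m)).astype(np.int8)
        ms = MaskSet()
        intervals = {
            "s00": [(20, 60)],
            "s01": [(50, 90), (150, 170)],
            "s02": [],
        }
        for s, ivs in intervals.items():
            ms._iv.setdefault(s, {})
            for a, b in ivs:
                ms.add(s, "chr1", a, b)
        g = ms.apply(make_matrix(calls, pos=pos))
        d = masked_pgd(g, masks=ms, chrom_lengths={"chr1": L})
        for i, j in itertools.combinations(range(n), 2):
            si, sj = g.sample_ids[i], g.sample_ids[j]
            denom = diffs = 0
            for x in range(1, L + 1):
                masked = any(a <= x <= b for a, b in intervals[si]) or any(
                    a <= x <= b for a, b in intervals[sj]
                )
                if masked:
                    continue
                denom += 1
                k = np.flatnonzero(pos == x)
                if len(k):
                    ci, cj = g.calls[i, k[0]], g.calls[j, k[0]]
                    if ci != MISSING and cj != MISSING and ci != cj:
                        diffs += 1
            assert d.n_observed[i, j] == denom
            assert d.dist[i, j] == pytest.approx(diffs / denom)

    def test_symmetry_and_permutation_invariance(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(-1, 2, size=(5, 50)).astype(np.int8)
        g = make_matrix(calls)
        d = masked_pgd(g)
        np.testing.assert_allclose(d.dist, d.dist.T)
        perm = [3, 1, 4, 0, 2]
        d2 = masked_pgd(g.take_samples(perm))
        for a in range(5):
            for b in range(5):
                assert d2.dist[a, b] == pytest.approx(d.dist[perm[a], perm[b]])


def _dm(ids, dist, nobs=None):
    dist = np.asarray(dist, dtype=float)
    if nobs is None:
        nobs = np.full_like(dist, 1000, dtype=np.int64)
    return DistanceMatrix(sample_ids=ids, dist=dist, n_observed=nobs)


class TestRelatednessFilter:
    def test_removes_more_missing_member(self):
        d = _dm(["A", "B"], [[0, 0.0005], [0.0005, 0]])
        kept = relatedness_filter(d, {"A": 100, "B": 10})
        assert kept == ["B"]

    def test_all_distant_pairs_retained(self):
        d = _dm(["A", "B", "C"], [[0, 0.001, 0.002], [0.001, 0, 0.003], [0.002, 0.003, 0]])
        assert relatedness_filter(d, {}) == ["A", "B", "C"]

    def test_default_threshold(self):
        import inspect

        sig = inspect.signature(relatedness_filter)
        assert sig.parameters["threshold"].default == 0.0007

    def test_result_is_maximal(self):
        rng = np.random.default_rng(2)
        n = 8
        ids = [f"s{i}" for i in range(n)]
        dist = rng.uniform(0, 0.002, size=(n, n))
        dist = (dist + dist.T) / 2
        np.fill_diagonal(dist, 0)
        miss = {s: int(rng.integers(0, 50)) for s in ids}
        kept = relatedness_filter(_dm(ids, dist), miss)
        idx = {s: i for i, s in enumerate(ids)}
        # no close pair remains
        for a, b in itertools.combinations(kept, 2):
            assert dist[idx[a], idx[b]] > 0.0007
        # every removed strain is close to some retained strain
        for s in set(ids) - set(kept):
            assert any(dist[idx[s], idx[k]] <= 0.0007 for k in kept)


class TestClassicalMds:
    def test_two_points(self):
        d = _dm(["A", "B"], [[0, 0.4], [0.4, 0]])
        coords, evals = classical_mds(d, k=1)
        np.testing.assert_allclose(np.abs(coords[:, 0]), 0.2, atol=1e-12)

    def test_right_triangle_distances_recovered(self):
        d = _dm(
            ["A", "B", "C"],
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]],
        )
        coords, _ = classical_mds(d, k=2)
        rec = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        np.testing.assert_allclose(rec, d.dist, atol=1e-9)

    def test_euclidean_embedding_exact(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(20, 2))
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        d = _dm([f"s{i}" for i in range(20)], dist)
        coords, _ = classical_mds(d, k=2)
        rec = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        np.testing.assert_allclose(rec, dist, atol=1e-6)


def _brute_complete_linkage(dist):
    """Naive agglomeration, returns sorted merge heights."""
    clusters = [frozenset([i]) for i in range(len(dist))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            h = max(dist[i][j] for i in clusters[a] for j in clusters[b])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        heights.append(h)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return sorted(heights)


class TestHierarchicalCluster:
    def test_first_split_separates_distant_groups(self):
        dist = np.full((4, 4), 0.001)
        dist[:2, 2:] = 0.01
        dist[2:, :2] = 0.01
        np.fill_diagonal(dist, 0)
        tree = hierarchical_cluster(_dm(list("ABCD"), dist))
        cut = tree.cut(n_groups=2)
        assert cut["A"] == cut["B"] and cut["C"] == cut["D"] and cut["A"] != cut["C"]

    def test_merge_heights_match_brute_force(self):
        rng = np.random.default_rng(7)
        dist = rng.uniform(0.1, 1.0, size=(5, 5))
        dist = (dist + dist.T) / 2
        np.fill_diagonal(dist, 0)
        tree = hierarchical_cluster(_dm([f"s{i}" for i in range(5)], dist), "complete")
        np.testing.assert_allclose(
            sorted(tree.merge_heights), _brute_complete_linkage(dist), atol=1e-12
        )

    def test_newick_has_all_leaves(self):
        dist = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        tree = hierarchical_cluster(_dm(["x", "y", "z"], dist))
        nwk = tree.to_newick()
        assert nwk.endswith(";") and all(leaf in nwk for leaf in "xyz")


class TestModeDetection:
    def test_degenerate_all_equal(self):
        d = _dm(list("ABC"), [[0, 0.3, 0.3], [0.3, 0, 0.3], [0.3, 0.3, 0]])
        rep = pgd_mode_detection(d)
        assert rep.n_modes == 1 and rep.modes[0] == pytest.approx(0.3)

    def test_two_gaussian_mixture_modes(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate(
            [rng.normal(0.004, 0.0004, 300), rng.normal(0.008, 0.0004, 300)]
        )
        # embed the values into a synthetic distance matrix's upper triangle
        n = 35  # 595 pairs
        dist = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        dist[iu] = vals[: len(iu[0])]
        dist = dist + dist.T
        d = _dm([f"s{i}" for i in range(n)], dist)
        rep = pgd_mode_detection(d)
        assert rep.n_modes == 2
        assert abs(rep.modes[0] - 0.004) < rep.bandwidth / 2 + 1e-4
        assert abs(rep.modes[1] - 0.008) < rep.bandwidth / 2 + 1e-4
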