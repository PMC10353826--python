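"""Masked pairwise genetic distances and population-structure utilities.

The pairwise genetic distance (PGD) between two strains is the number of
sites at which both carry a known call and differ, divided by the number of
genomic positions at which neither strain is masked.  A deeply diverged
("relict") subgroup shows up as a second, high-distance mode in the
distribution of PGD values; classical MDS and hierarchical clustering of the
PGD matrix then separate the groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import squareform
from scipy.stats import gaussian_kde

from .genotype import MISSING, GenotypeMatrix, MaskSet

__all__ = [
    "DistanceMatrix",
    "ClusterTree",
    "ModeReport",
    "masked_pgd",
    "relatedness_filter",
    "classical_mds",
    "hierarchical_cluster",
    "pgd_mode_detection",
]

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric PGD matrix with per-pair jointly observed site counts.

    ``dist`` entries are NaN where a pair had no jointly observed positions
    (undefined, not zero).
    """

    sample_ids: list[str]
    dist: np.ndarray
    n_observed: np.ndarray

    def __post_init__(self) -> None:
        self.dist = np.asarray(self.dist, dtype=float)
        self.n_observed = np.asarray(self.n_observed, dtype=np.int64)
        n = len(self.sample_ids)
        if self.dist.shape != (n, n) or self.n_observed.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def offdiag_values(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        vals = self.dist[iu]
        return vals[~np.isnan(vals)]

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("sample\t" + "\t".join(self.sample_ids) + "\n")
            for i, s in enumerate(self.sample_ids):
                row = "\t".join(f"{v:.8g}" for v in self.dist[i])
                fh.write(f"{s}\t{row}\n")


@dataclass
class ClusterTree:
    """Agglomerative tree over strains (scipy linkage encoding)."""

    linkage_matrix: np.ndarray
    leaf_labels: list[str]
    method: str

    def cut(self, n_groups: int | None = None, height: float | None = None) -> dict[str, int]:
        """Group labels from cutting the tree into ``n_groups`` or at ``height``."""
        if (n_groups is None) == (height is None):
            raise ValueError("give exactly one of n_groups or height")
        if n_groups is not None:
            lab = _hier.fcluster(self.linkage_matrix, t=n_groups, criterion="maxclust")
        else:
            lab = _hier.fcluster(self.linkage_matrix, t=height, criterion="distance")
        return dict(zip(self.leaf_labels, (int(v) for v in lab)))

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        tree = _hier.to_tree(self.linkage_matrix)

        def rec(node) -> str:
            if node.is_leaf():
                return self.leaf_labels[node.id]
            left, right = rec(node.left), rec(node.right)
            bl_l = node.dist - node.left.dist
            bl_r = node.dist - node.right.dist
            return f"({left}:{bl_l:.8g},{right}:{bl_r:.8g})"

        return rec(tree) + ";"


@dataclass
class ModeReport:
    """Modes of the PGD distribution from a kernel density estimate."""

    modes: np.ndarray  # locations, ascending
    masses: np.ndarray  # KDE mass attributed to each mode's basin
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    @property
    def n_modes(self) -> int:
        return len(self.modes)


def masked_pgd(
    g: GenotypeMatrix,
    masks: MaskSet | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> DistanceMatrix:
    """Pairwise genetic distances with mask-aware denominators.

    The numerator for a pair counts sites where both calls are known and
    differ.  With ``masks`` and ``chrom_lengths`` the denominator is the
    number of genome positions unmasked in both strains; without masks it is
    the number of jointly non-missing SNP sites (so the distance is the
    fraction of jointly observed SNPs that differ).

    SNP sites where either member of a pair is missing are excluded from the
    numerator; with masks they are also absent from the denominator whenever
    the missingness comes from a masked position.
    """
    n = g.n_samples
    obs = g.calls != MISSING
    x = g.calls.astype(np.int16)
    dist = np.zeros((n, n))
    nobs = np.zeros((n, n), dtype=np.int64)

    if masks is not None:
        if chrom_lengths is None:
            raise ValueError("chrom_lengths required when masks are given")
        genome_len = sum(chrom_lengths.values())

    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            diffs = int(np.sum((x[i] != x[j]) & both))
            if masks is not None:
                denom = genome_len
                for chrom in chrom_lengths:
                    u = masks.union_pair(g.sample_ids[i], g.sample_ids[j], chrom)
                    if len(u):
                        denom -= int((u[:, 1] - u[:, 0] + 1).sum())
            else:
                denom = int(both.sum())
            nobs[i, j] = nobs[j, i] = denom
            if denom == 0:
                dist[i, j] = dist[j, i] = np.nan
                log.warning(
                    "pair (%s, %s): no jointly observed positions",
                    g.sample_ids[i],
                    g.sample_ids[j],
                )
            else:
                dist[i, j] = dist[j, i] = diffs / denom
    return DistanceMatrix(sample_ids=list(g.sample_ids), dist=dist, n_observed=nobs)


def relatedness_filter(
    d: DistanceMatrix,
    missing_per_sample: dict[str, int],
    threshold: float = 0.0007,
) -> list[str]:
    """Drop one member of every closely related pair (PGD <= threshold).

    Pairs are processed in ascending PGD order; from each pair still present
    the strain with more missing data is removed (ties by lexicographically
    later sample id).  The retained set has no remaining pair at or below the
    threshold, and is maximal: any removed strain would re-create one.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ids = d.sample_ids
    iu = np.triu_indices(d.n, k=1)
    pairs = [
        (d.dist[a, b], ids[a], ids[b])
        for a, b in zip(*iu)
        if not np.isnan(d.dist[a, b]) and d.dist[a, b] <= threshold
    ]
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    removed: set[str] = set()
    for _, a, b in pairs:
        if a in removed or b in removed:
            continue
        ma, mb = missing_per_sample.get(a, 0), missing_per_sample.get(b, 0)
        if ma > mb:
            removed.add(a)
        elif mb > ma:
            removed.add(b)
        else:
            removed.add(max(a, b))
    return [s for s in ids if s not in removed]


def classical_mds(d: DistanceMatrix, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson principal coordinates analysis of the PGD matrix.

    Double-centers the squared distances, eigendecomposes, and returns
    coordinates built from the top-``k`` non-negative eigenvalues together
    with the full eigenvalue spectrum (descending).

    Returns
    -------
    (coords, eigenvalues) : (n, k') array and (n,) array
        ``k'`` may be less than ``k`` when fewer positive eigenvalues exist
        (a warning is logged).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if np.isnan(d.dist).any():
        raise ValueError("undefined distances present; drop those samples first")
    D2 = d.dist**2
    n = d.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int(np.sum(evals > 1e-12 * max(evals.max(), 1.0)))
    k_eff = min(k, n_pos)
    if k_eff < k:
        log.warning("classical_mds: only %d positive eigenvalues; k truncated", n_pos)
    coords = evecs[:, :k_eff] * np.sqrt(evals[:k_eff])
    return coords, evals


def hierarchical_cluster(d: DistanceMatrix, linkage: str = "complete") -> ClusterTree:
    """Agglomerative clustering of the PGD matrix."""
    if linkage not in ("complete", "average", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if np.isnan(d.dist).any():
        raise ValueError("undefined distances present; drop those samples first")
    condensed = squareform(d.dist, checks=False)
    Z = _hier.linkage(condensed, method=linkage)
    return ClusterTree(linkage_matrix=Z, leaf_labels=list(d.sample_ids), method=linkage)


def pgd_mode_detection(
    d: DistanceMatrix,
    bandwidth: float | None = None,
    mass_floor: float = 0.01,
    grid_points: int = 512,
) -> ModeReport:
    """Detect modes of the pairwise-distance distribution by KDE.

    Local maxima of a Gaussian KDE over all defined off-diagonal PGD values
    are reported when the mass in their basin (between flanking minima)
    exceeds ``mass_floor``.  Bandwidth defaults to Silverman's rule.
    """
    vals = d.offdiag_values()
    if len(vals) < 2:
        raise ValueError("need at least 2 defined pairwise distances")
    if np.allclose(vals, vals[0]):
        v = float(vals[0])
        return ModeReport(
            modes=np.array([v]),
            masses=np.array([1.0]),
            grid=np.array([v]),
            density=np.array([np.inf]),
            bandwidth=0.0,
        )
    kde = gaussian_kde(vals, bw_method="silverman" if bandwidth is None else None)
    if bandwidth is not None:
        kde.set_bandwidth(bandwidth / vals.std(ddof=1))
    bw = float(kde.factor * vals.std(ddof=1))
    lo, hi = vals.min() - 3 * bw, vals.max() + 3 * bw
    grid = np.linspace(lo, hi, grid_points)
    dens = kde(grid)
    # interior local maxima
    peaks = (
        np.flatnonzero((dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])) + 1
    )
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(dens))])
    # basin boundaries: minima between consecutive peaks
    bounds = [lo]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(grid[a + int(np.argmin(dens[a:b]))])
    bounds.append(hi)
    step = grid[1] - grid[0]
    modes, masses = [], []
    for p, (left, right) in zip(peaks, zip(bounds[:-1], bounds[1:])):
        in_basin = (grid >= left) & (grid <= right)
        mass = float(dens[in_basin].sum() * step)
        if mass >= mass_floor:
            modes.append(grid[p])
            masses.append(mass)
    order = np.argsort(modes)
    return ModeReport(
        modes=np.array(modes)[order],
        masses=np.array(masses)[order],
        grid=grid,
        density=dens,
        bandwidth=bw,
    )
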