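"""Composite-likelihood-ratio scan for recent hard selective sweeps.

The test compares, at each candidate position, the probability of the
observed derived-allele counts under a sweep-distorted site frequency
spectrum against the genome-wide background spectrum.  The sweep distortion
follows the star-like approximation: during the sweep each of the n sampled
lineages escapes to the pre-sweep background independently with probability
p_e = 1 - exp(-alpha * d), where d is the (recombination-scaled) distance
from the sweep site and alpha measures sweep strength (larger alpha = weaker
footprint at a given distance).  Lineages that fail to escape coalesce into
the single sweeping ancestor.

Significance thresholds come from the 95th percentile of per-replicate
maximum CLR values over neutral simulations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "BackgroundSFS",
    "CLRResult",
    "RecombinationMap",
    "sweep_spectrum",
    "sweep_transition_matrix",
    "clr_scan",
    "scan_sites_from_matrix",
    "clr_threshold",
    "default_alpha_grid",
    "write_site_file",
    "read_site_file",
]

log = logging.getLogger(__name__)


@dataclass
class BackgroundSFS:
    """Background probabilities q_j of derived class j = 0..n.

    When ``includes_invariant`` is False, classes 0 and n carry zero mass and
    the spectrum is normalized over 1..n-1 (scan restricted to polymorphic
    sites).
    """

    n: int
    probs: np.ndarray
    includes_invariant: bool = False

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.probs) != self.n + 1:
            raise ValueError(f"probs must have length n+1 = {self.n + 1}")
        if (self.probs < 0).any():
            raise ValueError("negative probabilities")
        if not self.includes_invariant:
            self.probs = self.probs.copy()
            self.probs[0] = 0.0
            self.probs[self.n] = 0.0
        total = self.probs.sum()
        if total <= 0:
            raise ValueError("empty spectrum")
        self.probs = self.probs / total

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        includes_invariant: bool = False,
        pseudocount: float = 0.0,
    ) -> "BackgroundSFS":
        """Build from class counts; ``pseudocount`` is added to every
        variant class so classes unobserved in a finite background panel
        keep non-zero mass."""
        counts = np.asarray(counts, dtype=float).copy()
        if pseudocount:
            counts[1:-1] += pseudocount
            if includes_invariant:
                counts[-1] += pseudocount
        return cls(n=len(counts) - 1, probs=counts, includes_invariant=includes_invariant)


@dataclass
class CLRResult:
    """CLR and maximizing sweep-strength parameter at one test position."""

    position: int
    clr: float
    alpha_hat: float


class RecombinationMap:
    """Piecewise-constant per-bp recombination rate along one chromosome.

    ``segments`` is a list of (start, end, rate) with 1-based inclusive
    coordinates; the recombination distance between two positions is the
    integral of the rate between them.  The default single-segment unit-rate
    map makes distance equal physical distance (alpha absorbs the rate).
    """

    def __init__(self, segments: list[tuple[int, int, float]] | None = None):
        if segments is None:
            segments = [(1, 2**62, 1.0)]
        segments = sorted(segments)
        starts = np.array([s for s, _, _ in segments], dtype=float)
        ends = np.array([e for _, e, _ in segments], dtype=float)
        rates = np.array([r for _, _, r in segments], dtype=float)
        if (rates < 0).any():
            raise ValueError("negative recombination rate")
        if np.any(starts[1:] <= ends[:-1]) and len(segments) > 1:
            # allow adjacent (end+1 == next start) but not overlapping
            if np.any(starts[1:] <= ends[:-1]):
                raise ValueError("overlapping recombination-map segments")
        self.starts, self.ends, self.rates = starts, ends, rates
        # cumulative map position at each segment start
        seg_len = ends - starts + 1
        self._cum = np.concatenate([[0.0], np.cumsum(seg_len * rates)])

    def map_position(self, pos) -> np.ndarray:
        """Cumulative recombination distance from the map origin."""
        pos = np.asarray(pos, dtype=float)
        i = np.clip(np.searchsorted(self.starts, pos, side="right") - 1, 0, len(self.starts) - 1)
        within = np.clip(pos - self.starts[i], 0.0, self.ends[i] - self.starts[i] + 1)
        return self._cum[i] + within * self.rates[i]

    def distance(self, a, b) -> np.ndarray:
        return np.abs(self.map_position(a) - self.map_position(b))


def sweep_transition_matrix(q: BackgroundSFS) -> np.ndarray:
    """M[k, b] = P(modern derived count b | k lineages escaped the sweep).

    Independent of distance and alpha: with k < n escapees the ancestral
    sample holds m = k + 1 lineages (k escapees plus the sweeping ancestor);
    the ancestral derived count j' follows hypergeometric downsampling of the
    background spectrum from n to m; the sweeping ancestor is derived with
    probability j'/m, in which case its n - k modern descendants are all
    derived (b = j' + n - k - 1), else b = j'.  With k = n everything escaped
    and b is a draw from the background itself.
    """
    n = q.n
    qp = q.probs
    lg = gammaln(np.arange(2 * n + 2) + 1.0)

    def log_comb(a, b):
        return lg[a] - lg[b] - lg[a - b]

    M = np.zeros((n + 1, n + 1))
    M[n] = qp
    for k in range(n):
        m = k + 1
        # downsample q from n to m
        down = np.zeros(m + 1)
        for jp in range(m + 1):
            acc = 0.0
            for j in range(jp, n - m + jp + 1):
                if j < 0 or j > n:
                    continue
                acc += qp[j] * np.exp(
                    log_comb(j, jp) + log_comb(n - j, m - jp) - log_comb(n, m)
                )
            down[jp] = acc
        for jp in range(m + 1):
            p_der = jp / m
            if p_der > 0:
                b = jp + n - k - 1
                M[k, b] += down[jp] * p_der
            if p_der < 1:
                M[k, jp] += down[jp] * (1 - p_der)
    return M


def _escape_weights(n: int, p_e: np.ndarray) -> np.ndarray:
    """Binomial(n, p_e) pmf rows for an array of escape probabilities."""
    k = np.arange(n + 1)
    lg = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    p = np.clip(np.asarray(p_e, dtype=float), 1e-300, 1.0)[:, None]
    with np.errstate(divide="ignore"):
        logpmf = lg[None, :] + k[None, :] * np.log(p) + (n - k)[None, :] * np.log1p(-np.clip(p, 0, 1 - 1e-16))
    w = np.exp(logpmf)
    # exact boundaries
    w[np.asarray(p_e) >= 1.0] = 0.0
    w[np.asarray(p_e) >= 1.0, n] = 1.0
    w[np.asarray(p_e) <= 0.0] = 0.0
    w[np.asarray(p_e) <= 0.0, 0] = 1.0
    return w


def sweep_spectrum(q: BackgroundSFS, d: float, alpha: float) -> np.ndarray:
    """Modern derived-count distribution at recombination distance d from a
    sweep of strength alpha.

    With invariant classes excluded from q, the output is likewise
    conditioned on polymorphism (classes 0 and n zeroed, renormalized).
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    with np.errstate(over="ignore"):
        p_e = float(-np.expm1(-np.clip(alpha * d, 0.0, 700.0)))
    M = sweep_transition_matrix(q)
    w = _escape_weights(q.n, np.array([p_e]))[0]
    out = w @ M
    if not q.includes_invariant:
        out = out.copy()
        out[0] = 0.0
        out[q.n] = 0.0
        s = out.sum()
        if s > 0:
            out = out / s
    return out


def default_alpha_grid(
    median_distance: float,
    n_points: int = 40,
    min_distance: float | None = None,
    max_distance: float | None = None,
) -> np.ndarray:
    """Log-spaced alpha values covering weak to strong sweep footprints.

    The grid spans from "1% escape at the largest site distance" (a footprint
    engulfing the whole region) to "99% escape at the smallest non-zero
    distance" (a footprint narrower than the site spacing), so the scan's
    maximization brackets any realizable footprint width.
    """
    if median_distance <= 0:
        median_distance = 1.0
    d_lo = max_distance if max_distance and max_distance > 0 else median_distance
    d_hi = min_distance if min_distance and min_distance > 0 else median_distance
    lo = -np.log(1 - 0.01) / d_lo
    hi = -np.log(1 - 0.99) / d_hi
    if hi <= lo:
        hi = lo * 100
    return np.geomspace(lo, hi, n_points)


def clr_scan(
    positions: np.ndarray,
    derived_counts: np.ndarray,
    q: BackgroundSFS,
    grid_step: int = 10_000,
    alpha_grid: np.ndarray | None = None,
    rec_map: RecombinationMap | None = None,
    grid_positions: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> list[CLRResult]:
    """Composite-likelihood-ratio scan along a chromosome.

    At each grid position x, CLR(x) = 2 * [max_alpha sum_i w_i log P(b_i |
    d_i, alpha) - sum_i w_i log q_{b_i}] with d_i the recombination distance
    between x and site i.  ``weights`` default to 1 per site; a monomorphic
    grid site produced by :func:`scan_sites_from_matrix` carries the number
    of invariant positions it stands for.  The background model itself is
    always a candidate, so the CLR is non-negative.
    """
    positions = np.asarray(positions, dtype=np.int64)
    derived_counts = np.asarray(derived_counts, dtype=np.int64)
    if len(positions) == 0:
        raise ValueError("empty site list")
    if len(positions) != len(derived_counts):
        raise ValueError("positions / derived_counts length mismatch")
    w_sites = (
        np.ones(len(positions)) if weights is None else np.asarray(weights, dtype=float)
    )
    if not q.includes_invariant and (
        (derived_counts == 0).any() or (derived_counts == q.n).any()
    ):
        raise ValueError(
            "invariant sites supplied but background spectrum excludes them"
        )
    rm = rec_map if rec_map is not None else RecombinationMap()
    if grid_positions is None:
        grid_positions = np.arange(positions.min(), positions.max() + 1, grid_step)
    site_map = rm.map_position(positions)
    if alpha_grid is None:
        med = float(np.median(np.abs(site_map - np.median(site_map))))
        gaps = np.diff(np.unique(site_map))
        d_min = float(gaps.min()) if len(gaps) else med
        d_max = float(site_map.max() - site_map.min()) or med
        alpha_grid = default_alpha_grid(
            max(med, 1e-12), min_distance=d_min, max_distance=d_max
        )

    M = sweep_transition_matrix(q)  # (n+1, n+1)
    n = q.n
    qp = q.probs
    log_q = np.log(np.clip(qp, 1e-300, None))
    ll0 = float((w_sites * log_q[derived_counts]).sum())
    Mb = M[:, derived_counts]  # (n+1, sites) transition mass into observed class

    results: list[CLRResult] = []
    for x in grid_positions:
        xmap = float(rm.map_position(np.array([x]))[0])
        d = np.abs(site_map - xmap)
        best_ll = ll0  # background model candidate (alpha -> infinity)
        best_alpha = float("inf")
        for alpha in alpha_grid:
            with np.errstate(over="ignore"):
                p_e = -np.expm1(-np.clip(alpha * d, 0.0, 700.0))
            W = _escape_weights(n, p_e)  # (sites, n+1)
            probs = np.einsum("sk,ks->s", W, Mb)
            if not q.includes_invariant:
                # renormalize over polymorphic classes per site
                poly_mass = 1.0 - W @ (M[:, 0] + M[:, n])
                probs = probs / np.clip(poly_mass, 1e-300, None)
            ll = float((w_sites * np.log(np.clip(probs, 1e-300, None))).sum())
            if ll > best_ll:
                best_ll = ll
                best_alpha = float(alpha)
        results.append(CLRResult(int(x), 2.0 * (best_ll - ll0), best_alpha))
    return results


def scan_sites_from_matrix(
    g,
    total_callable: int,
    invariant_spacing: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, BackgroundSFS]:
    """Build scan inputs (positions, counts, weights, background spectrum)
    from a derived-coded genotype matrix.

    With ``invariant_spacing``, monomorphic positions enter the scan: grid
    sites with derived count 0 are placed every ``invariant_spacing`` bp
    between the observed sites, each weighted by the number of invariant
    positions it represents, and the background spectrum includes the
    invariant class (padded to ``total_callable``).  Without it, only the
    polymorphic sites are used and the spectrum excludes invariant classes.
    """
    from .diversity import sfs as _sfs

    all_counts = (g.calls == 1).sum(axis=0)
    n = g.n_samples
    poly = (all_counts > 0) & (all_counts < n)
    if invariant_spacing is None:
        positions = g.pos[poly].astype(np.int64)
        counts = all_counts[poly].astype(np.int64)
        spec = _sfs(g.take_sites(np.flatnonzero(poly)))
        q = BackgroundSFS.from_counts(spec.counts, includes_invariant=False)
        return positions, counts, np.ones(len(positions)), q
    # with invariant classes, fixed-derived sites (class n) stay in the scan
    used = all_counts > 0
    positions = g.pos[used].astype(np.int64)
    counts = all_counts[used].astype(np.int64)
    spec = _sfs(g, include_invariant=True, total_callable=total_callable)
    q = BackgroundSFS.from_counts(spec.counts, includes_invariant=True)
    lo, hi = 1, total_callable
    grid = np.arange(lo, hi + 1, invariant_spacing, dtype=np.int64)
    grid = grid[~np.isin(grid, positions)]
    n_invariant = total_callable - len(positions)
    w_grid = np.full(len(grid), n_invariant / max(len(grid), 1))
    all_pos = np.concatenate([positions, grid])
    all_cnt = np.concatenate([counts, np.zeros(len(grid), dtype=np.int64)])
    all_w = np.concatenate([np.ones(len(positions)), w_grid])
    order = np.argsort(all_pos, kind="stable")
    return all_pos[order], all_cnt[order], all_w[order], q


def clr_threshold(
    neutral_replicates: list[tuple[np.ndarray, np.ndarray]],
    q: BackgroundSFS,
    percentile: float = 95.0,
    **scan_kwargs,
) -> float:
    """Significance threshold from neutral simulations.

    Each replicate is a (positions, derived_counts) pair; the scan runs on
    each, the per-replicate maximum CLR is collected, and the requested
    percentile (linear interpolation) is returned.
    """
    if len(neutral_replicates) < 20:
        log.warning(
            "clr_threshold: only %d replicates; >= 20 recommended",
            len(neutral_replicates),
        )
    maxima = []
    for positions, counts in neutral_replicates:
        res = clr_scan(positions, counts, q, **scan_kwargs)
        maxima.append(max(r.clr for r in res))
    return float(np.percentile(maxima, percentile))


def write_site_file(path: str, positions, derived_counts, n: int, folded: bool = False) -> None:
    """Write a sweep-scan site file (position, x, n, folded columns)."""
    with open(path, "w") as fh:
        fh.write("position\tx\tn\tfolded\n")
        for p, x in zip(positions, derived_counts):
            fh.write(f"{int(p)}\t{int(x)}\t{n}\t{int(folded)}\n")


def read_site_file(path: str) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Read a sweep-scan site file; returns (positions, counts, n, folded)."""
    pos, cnt, ns, folded = [], [], set(), False
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("position"):
            raise ValueError("missing site-file header")
        for line in fh:
            if not line.strip():
                continue
            f = line.split()
            pos.append(int(f[0]))
            cnt.append(int(f[1]))
            ns.add(int(f[2]))
            folded = bool(int(f[3]))
    if len(ns) != 1:
        raise ValueError("inconsistent sample sizes in site file")
    return (
        np.array(pos, dtype=np.int64),
        np.array(cnt, dtype=np.int64),
        ns.pop(),
        folded,
    )
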