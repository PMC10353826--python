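"""Windowed and global diversity / differentiation statistics.

Implements the unfolded site frequency spectrum with outgroup polarization,
nucleotide diversity (pi), Watterson's theta, Tajima's D, Weir & Cockerham
(1984) weighted FST, and linkage-disequilibrium decay, all on haploid-coded
genotype matrices.

Window convention: half-open tiling [start, start + span) in 1-based
coordinates, first window starting at position 1, advancing by the stride.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotype import MISSING, GenotypeMatrix, MaskSet

__all__ = [
    "SiteFrequencySpectrum",
    "WindowStat",
    "LDBin",
    "polarize",
    "sfs",
    "fold_sfs",
    "site_pi",
    "watterson_theta",
    "pi_window",
    "tajimas_d",
    "tajima_constants",
    "tajimas_d_window",
    "wc_fst_components",
    "wc_fst_window",
    "wc_fst_global",
    "ld_decay",
    "exclude_intervals",
    "windows_for",
]

log = logging.getLogger(__name__)


@dataclass
class SiteFrequencySpectrum:
    """Counts of derived-allele classes j = 0..n.

    ``counts[j]`` is the number of sites with j derived copies among the n
    sampled haplotypes.  ``includes_invariant`` records whether classes 0
    (and n) carry monomorphic-site mass.
    """

    n: int
    counts: np.ndarray
    folded: bool = False
    includes_invariant: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        expected = self.n // 2 + 1 if self.folded else self.n + 1
        if len(self.counts) != expected:
            raise ValueError(
                f"counts length {len(self.counts)} != {expected} for n={self.n}"
            )
        if (self.counts < 0).any():
            raise ValueError("negative SFS counts")

    def probabilities(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("empty spectrum")
        return self.counts / total

    def to_table(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("class\tcount\n")
            for j, c in enumerate(self.counts):
                fh.write(f"{j}\t{c}\n")


@dataclass
class WindowStat:
    """One window's statistic (value is NaN when undefined)."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    n_sites: int
    callable_sites: int
    value: float


@dataclass
class LDBin:
    """Mean r^2 of SNP pairs whose distance falls in [low, high) bp."""

    low: int
    high: int
    mean_r2: float
    n_pairs: int


# ---------------------------------------------------------------------------
# Polarization and the SFS


def polarize(
    g: GenotypeMatrix, outgroup_calls: np.ndarray
) -> tuple[GenotypeMatrix, int]:
    """Recode the matrix so 1 means the derived allele.

    ``outgroup_calls`` holds, per site, the outgroup allele: 0 (matches ref),
    1 (matches alt) or MISSING/other.  Sites where the outgroup carries the
    alternate allele are flipped (0 <-> 1, ref/alt swapped); sites with a
    missing or third-state outgroup call are dropped.

    Returns the polarized matrix and the number of unpolarizable sites
    dropped.
    """
    out = np.asarray(outgroup_calls)
    if len(out) != g.n_sites:
        raise ValueError("outgroup_calls length mismatch")
    keep = (out == 0) | (out == 1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("polarize: dropped %d unpolarizable sites", n_dropped)
    flip = out == 1
    calls = g.calls.copy()
    obs = calls != MISSING
    cols = np.flatnonzero(flip)
    for c in cols:
        m = obs[:, c]
        calls[m, c] = 1 - calls[m, c]
    ref = g.ref_allele.copy()
    alt = g.alt_allele.copy()
    ref[cols], alt[cols] = g.alt_allele[cols], g.ref_allele[cols]
    from dataclasses import replace

    g2 = replace(g, calls=calls, ref_allele=ref, alt_allele=alt)
    return g2.take_sites(np.flatnonzero(keep)), n_dropped


def sfs(
    g: GenotypeMatrix,
    subset: list[str] | None = None,
    include_invariant: bool = False,
    total_callable: int | None = None,
) -> SiteFrequencySpectrum:
    """Unfolded SFS over fully observed sites in a sample subset.

    Sites with any missing call in the subset are dropped (logged).  With
    ``include_invariant``, class 0 is padded so the total equals
    ``total_callable`` (monomorphic sites included, as a composite-likelihood
    scan over all positions requires).
    """
    sub = g if subset is None else g.take_samples(subset)
    n = sub.n_samples
    complete = ~(sub.calls == MISSING).any(axis=0)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("sfs: dropped %d sites with missing calls", n_dropped)
    derived = (sub.calls[:, complete] == 1).sum(axis=0)
    counts = np.bincount(derived, minlength=n + 1).astype(np.int64)
    if include_invariant:
        if total_callable is None:
            raise ValueError("total_callable required with include_invariant")
        n_used = int(complete.sum())
        if total_callable < n_used:
            raise ValueError("total_callable smaller than number of sites used")
        counts[0] += total_callable - n_used
    return SiteFrequencySpectrum(
        n=n, counts=counts, folded=False, includes_invariant=include_invariant
    )


def fold_sfs(s: SiteFrequencySpectrum) -> SiteFrequencySpectrum:
    """Fold an unfolded spectrum to minor-allele classes m = 0..n//2."""
    if s.folded:
        return s
    n = s.n
    folded = np.zeros(n // 2 + 1, dtype=np.int64)
    for j, c in enumerate(s.counts):
        m = min(j, n - j)
        folded[m] += c
    return SiteFrequencySpectrum(
        n=n, counts=folded, folded=True, includes_invariant=s.includes_invariant
    )


# ---------------------------------------------------------------------------
# Windows


def windows_for(
    chrom_positions: np.ndarray, span: int, stride: int, chrom_length: int | None = None
) -> list[tuple[int, int]]:
    """[start, end] 1-based inclusive windows tiling a chromosome."""
    if not (span >= stride >= 1):
        raise ValueError("require span >= stride >= 1")
    last = chrom_length if chrom_length is not None else int(chrom_positions.max())
    out = []
    start = 1
    while start <= last:
        out.append((start, start + span - 1))
        start += stride
    return out


def _per_site_pi_terms(calls: np.ndarray) -> np.ndarray:
    """Per-site heterozygosity 2*c*(n_s - c) / (n_s*(n_s - 1)) with
    pairwise-complete sample sizes (sites with n_s < 2 contribute 0)."""
    obs = calls != MISSING
    n_s = obs.sum(axis=0)
    c = (calls == 1).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = 2.0 * c * (n_s - c) / (n_s * (n_s - 1.0))
    t[n_s < 2] = 0.0
    return t


def site_pi(g: GenotypeMatrix) -> np.ndarray:
    """Per-site nucleotide diversity terms (unnormalized)."""
    return _per_site_pi_terms(g.calls)


def _callable_in_window(
    masks: MaskSet | None,
    sample_ids: list[str],
    chrom: str,
    start: int,
    end: int,
    chrom_length: int | None,
) -> int:
    """Window positions observable in every sample (masked-aware); plain
    window length when no masks are given."""
    hi = end if chrom_length is None else min(end, chrom_length)
    length = hi - start + 1
    if length <= 0:
        return 0
    if masks is None:
        return length
    covered = np.zeros(length, dtype=bool)
    for s in sample_ids:
        iv = masks.intervals(s, chrom)
        for a, b in iv:
            lo = max(int(a), start)
            hi2 = min(int(b), hi)
            if lo <= hi2:
                covered[lo - start : hi2 - start + 1] = True
    return int(length - covered.sum())


def pi_window(
    g: GenotypeMatrix,
    masks: MaskSet | None = None,
    span: int = 100_000,
    stride: int = 100_000,
    chrom_lengths: dict[str, int] | None = None,
) -> list[WindowStat]:
    """Windowed nucleotide diversity per site.

    Pi in a window is the sum of per-site pairwise heterozygosities (with
    pairwise-complete sample sizes) divided by the callable positions: the
    masked-aware count when ``masks`` are supplied, else the window length.
    Windows with zero callable positions get NaN.
    """
    terms = _per_site_pi_terms(g.calls)
    out: list[WindowStat] = []
    for chrom in dict.fromkeys(g.chrom):
        sel = g.chrom == chrom
        pos = g.pos[sel]
        t = terms[sel]
        clen = chrom_lengths.get(str(chrom)) if chrom_lengths else None
        for start, end in windows_for(pos, span, stride, clen):
            in_w = (pos >= start) & (pos <= end)
            callable_n = _callable_in_window(
                masks, g.sample_ids, str(chrom), start, end, clen
            )
            value = float(t[in_w].sum() / callable_n) if callable_n > 0 else np.nan
            out.append(
                WindowStat(str(chrom), start, end, int(in_w.sum()), callable_n, value)
            )
    return out


# ---------------------------------------------------------------------------
# Tajima's D


def tajima_constants(n: int) -> dict[str, float]:
    """The canonical a1, a2, b1, b2, c1, c2, e1, e2 for sample size n."""
    if n < 2:
        raise ValueError("n must be >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def watterson_theta(S: int, n: int, callable_sites: int | None = None) -> float:
    """Watterson's estimator S / a1, per site when ``callable_sites`` given."""
    if n < 2:
        raise ValueError("n must be >= 2")
    theta = S / tajima_constants(n)["a1"]
    return theta / callable_sites if callable_sites else theta


def tajimas_d(pi_sum: float, S: int, n: int) -> float:
    """Tajima (1989) D from the pairwise-diversity sum, the number of
    segregating sites and the sample size.  NaN when S = 0."""
    if S == 0:
        return float("nan")
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return float((pi_sum - S / k["a1"]) / np.sqrt(var))


def tajimas_d_window(
    g: GenotypeMatrix,
    span: int = 200_000,
    stride: int = 50_000,
    chrom_lengths: dict[str, int] | None = None,
) -> list[WindowStat]:
    """Windowed Tajima's D on complete-case sites.

    Sites with any missing call are dropped so the sample size n is constant;
    windows without segregating sites report NaN (undefined, not zero).
    """
    n = g.n_samples
    if n < 4:
        log.warning("tajimas_d_window: n=%d samples is small for D", n)
    complete = ~(g.calls == MISSING).any(axis=0)
    c = (g.calls == 1).sum(axis=0)
    seg = complete & (c > 0) & (c < n)
    terms = np.where(seg, 2.0 * c * (n - c) / (n * (n - 1.0)), 0.0)
    out: list[WindowStat] = []
    for chrom in dict.fromkeys(g.chrom):
        sel = g.chrom == chrom
        pos = g.pos[sel]
        t = terms[sel]
        s_flag = seg[sel]
        clen = chrom_lengths.get(str(chrom)) if chrom_lengths else None
        for start, end in windows_for(pos, span, stride, clen):
            in_w = (pos >= start) & (pos <= end)
            S = int(s_flag[in_w].sum())
            value = tajimas_d(float(t[in_w].sum()), S, n)
            out.append(
                WindowStat(str(chrom), start, end, S, end - start + 1, value)
            )
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham FST


def wc_fst_components(
    g: GenotypeMatrix, pop_labels: dict[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir & Cockerham (1984) variance components.

    Haploid-coded strains are expanded to homozygous diploids, so the
    observed heterozygosity term is zero.  Sites with any missing call among
    the labelled samples are dropped (complete-case, NaN components).
    Returns (a, a + b + c) per site.
    """
    pops = sorted(set(pop_labels.values()))
    r = len(pops)
    if r < 2:
        raise ValueError("need at least 2 populations")
    sample_pop = np.array([pop_labels.get(s) for s in g.sample_ids], dtype=object)
    labelled = np.array([sp is not None for sp in sample_pop])
    obs = g.calls != MISSING
    alt = g.calls == 1
    complete = obs[labelled].all(axis=0)
    n_i = np.zeros((r, g.n_sites))
    p_i = np.zeros((r, g.n_sites))
    for k, popname in enumerate(pops):
        rows = sample_pop == popname
        n_i[k] = obs[rows].sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_i[k] = np.where(n_i[k] > 0, alt[rows].sum(axis=0) / np.maximum(n_i[k], 1), 0.0)
    valid = complete & ((n_i >= 2).sum(axis=0) >= 2)
    n_bar = n_i.mean(axis=0)
    n_total = n_i.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_bar = (n_i * p_i).sum(axis=0) / n_total
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        n_c = (n_total - (n_i**2).sum(axis=0) / n_total) / (r - 1)
        h_bar = 0.0  # homozygous diploids
        a = (n_bar / n_c) * (
            s2
            - 1.0
            / (n_bar - 1)
            * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2.0 * np.ones_like(a)
    tot = a + b + c
    a = np.where(valid, a, np.nan)
    tot = np.where(valid, tot, np.nan)
    return a, tot


def wc_fst_global(g: GenotypeMatrix, pop_labels: dict[str, str]) -> float:
    """Genome-wide weighted FST: sum(a) / sum(a + b + c) over usable sites."""
    a, tot = wc_fst_components(g, pop_labels)
    ok = ~np.isnan(tot)
    denom = float(tot[ok].sum())
    if denom == 0:
        return float("nan")
    return float(a[ok].sum() / denom)


def wc_fst_window(
    g: GenotypeMatrix,
    pop_labels: dict[str, str],
    span: int = 100_000,
    stride: int = 100_000,
    min_snps: int | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> list[WindowStat]:
    """Windowed weighted Weir-Cockerham FST, sum(a)/sum(a+b+c) per window.

    With ``min_snps`` (e.g. 700), windows with that many usable SNPs or fewer
    are omitted, mirroring the practice of excluding alignment-gap windows.
    """
    a, tot = wc_fst_components(g, pop_labels)
    ok = ~np.isnan(tot)
    out: list[WindowStat] = []
    for chrom in dict.fromkeys(g.chrom):
        sel = g.chrom == chrom
        pos = g.pos[sel]
        a_c, tot_c, ok_c = a[sel], tot[sel], ok[sel]
        clen = chrom_lengths.get(str(chrom)) if chrom_lengths else None
        for start, end in windows_for(pos, span, stride, clen):
            in_w = (pos >= start) & (pos <= end) & ok_c
            n_snps = int(in_w.sum())
            if min_snps is not None and n_snps <= min_snps:
                continue
            denom = float(tot_c[in_w].sum())
            value = float(a_c[in_w].sum() / denom) if denom != 0 else np.nan
            out.append(
                WindowStat(str(chrom), start, end, n_snps, end - start + 1, value)
            )
    return out


# ---------------------------------------------------------------------------
# LD decay


def ld_decay(
    g: GenotypeMatrix, max_dist: int = 300_000, bin_width: int = 10_000
) -> list[LDBin]:
    """Mean r^2 of within-chromosome SNP pairs against physical distance.

    All pairs at distance <= ``max_dist`` contribute to contiguous distance
    bins of ``bin_width`` bp.
    """
    edges = np.arange(0, max_dist + bin_width, bin_width)
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    obs = g.calls != MISSING
    x = g.calls.astype(float)
    for chrom in dict.fromkeys(g.chrom):
        sel = np.flatnonzero(g.chrom == chrom)
        pos = g.pos[sel]
        for ii, i in enumerate(sel):
            j_hi = np.searchsorted(pos, pos[ii] + max_dist, side="right")
            for jj in range(ii + 1, j_hi):
                j = sel[jj]
                dist = int(pos[jj] - pos[ii])
                m = obs[:, i] & obs[:, j]
                if m.sum() < 2:
                    continue
                xi, xj = x[m, i], x[m, j]
                if xi.var() == 0 or xj.var() == 0:
                    continue
                r = np.corrcoef(xi, xj)[0, 1]
                b = min(int(dist // bin_width), len(sums) - 1)
                sums[b] += r * r
                counts[b] += 1
    out = []
    for b in range(len(sums)):
        mean = float(sums[b] / counts[b]) if counts[b] else float("nan")
        out.append(LDBin(int(edges[b]), int(edges[b + 1]), mean, int(counts[b])))
    return out


def exclude_intervals(
    g: GenotypeMatrix, intervals: list[tuple[str, int, int]]
) -> GenotypeMatrix:
    """Drop sites inside any (chrom, start, end) 1-based inclusive interval.

    Generic interval exclusion used for exon or pericentromere filtering
    (the interval list typically comes from a BED file, converted upstream).
    """
    drop = np.zeros(g.n_sites, dtype=bool)
    for chrom, start, end in intervals:
        drop |= (g.chrom == chrom) & (g.pos >= start) & (g.pos <= end)
    return g.take_sites(np.flatnonzero(~drop))
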