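"""Forward Wright-Fisher simulation of a hard sweep under partial selfing.

A diploid population of N individuals evolves on a single chromosome with a
piecewise-constant recombination map (chromosome arms vs. a low-recombining
pericentromere).  Each offspring is produced by self-fertilization with
probability sigma, else by two random parents; gametes recombine with
crossovers drawn per map segment and acquire new neutral mutations at rate
mu per bp (infinite-sites, continuous positions).  A beneficial mutation
(fitnesses 1, 1+hs, 1+s; recessive by default, h=0) is introduced as a
single copy a chosen number of generations before present; replicates in
which it is lost or ends below an acceptance frequency are discarded and
re-run.

High selfing raises homozygosity (F = sigma/(2-sigma)), lowers the effective
population size to N/(1+F) and suppresses effective recombination by
(1 - F), which is what makes selfing sweeps so wide.

The per-site diversity profile around the selected site gives the sweep
footprint; two estimators measure its physical extent: a window rule
(contiguous run of windows below the diversity of a distant reference
region) and a piecewise-linear (one hinge per flank) regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from numba import njit

from .diversity import WindowStat

__all__ = [
    "SimParams",
    "HaplotypePopulation",
    "SweepExtent",
    "full_scale_params",
    "desk_preset",
    "rescale",
    "footprint_preset",
    "run_forward",
    "run_neutral",
    "pi_profile",
    "sweep_extent_windows",
    "sweep_size_piecewise",
    "grid_experiment",
]

log = logging.getLogger(__name__)

#: chromosome length of the full-scale model (bp)
FULL_LENGTH = 18_747_412
#: arm / pericentromere recombination rates (per bp per generation)
ARM_RATE = 9.944e-8
PERI_RATE = 4.945e-9
#: pericentromere span of the full-scale model; the selected site sits at its
#: distal edge (package choice consistent with the sweep region's geometry)
PERI_SPAN = (5_000_000, 11_200_000)
#: selected-site position (bp) and empirical acceptance frequency
SEL_POS = 11_100_000
FREQ_THRESHOLD = 0.7931


@dataclass
class SimParams:
    """Forward-simulation parameters (one chromosome).

    ``rec_map`` is a list of (start, end, rate) 1-based inclusive segments
    covering [1, L]; rates in crossovers per bp per generation.
    """

    N: int
    L: int
    rec_map: list[tuple[int, int, float]]
    mu: float
    sel_pos: int
    s: float
    h: float = 0.0
    selfing: float = 0.95
    t_intro: int = 16_030
    burn_in: int | None = None  # default 10 * N
    freq_threshold: float = FREQ_THRESHOLD
    rescale_q: float = 1.0
    retry_cap: int = 1000
    # suggested analysis windows, rescaled along with the chromosome
    pi_window: int = 200_000
    pi_stride: int = 25_000

    def __post_init__(self) -> None:
        if not (0 <= self.selfing <= 1):
            raise ValueError("selfing must be in [0, 1]")
        if not (0 <= self.h <= 1):
            raise ValueError("h must be in [0, 1]")
        if any(r < 0 for _, _, r in self.rec_map):
            raise ValueError("negative recombination rate")
        if self.rescale_q < 1:
            raise ValueError("rescale factor must be >= 1")

    @property
    def inbreeding_f(self) -> float:
        """Equilibrium inbreeding coefficient F = sigma / (2 - sigma)."""
        return self.selfing / (2.0 - self.selfing)

    @property
    def n_effective(self) -> float:
        """Selfing-adjusted effective size N / (1 + F)."""
        return self.N / (1.0 + self.inbreeding_f)

    @property
    def effective_burn_in(self) -> int:
        return self.burn_in if self.burn_in is not None else 10 * self.N


#: full-scale census size: chosen so that the selfing-adjusted effective
#: size N/(1+F) ~ 31,000 reproduces the observed per-site nucleotide
#: diversity of the focal population (pi ~ 5e-4 with mu = 4e-9)
FULL_N = 60_000


def full_scale_params(s: float = 0.01, t_intro: int = 16_030) -> SimParams:
    """The full-scale single-chromosome model (not desk-feasible as is)."""
    return SimParams(
        N=FULL_N,
        L=FULL_LENGTH,
        rec_map=[
            (1, PERI_SPAN[0] - 1, ARM_RATE),
            (PERI_SPAN[0], PERI_SPAN[1], PERI_RATE),
            (PERI_SPAN[1] + 1, FULL_LENGTH, ARM_RATE),
        ],
        mu=4e-9,
        sel_pos=SEL_POS,
        s=s,
        t_intro=t_intro,
    )


def rescale(params: SimParams, Q: float) -> SimParams:
    """Population-rescaling by factor Q.

    N -> N/Q, generations -> gen/Q, s -> s*Q, mu -> mu*Q, r -> r*Q; selfing
    and dominance unchanged.  Theta = 4*N*mu and rho = 4*N*r are invariant.
    Large Q distorts the selfing-drift interplay (rare outcross events are
    compressed), so keep Q modest.
    """
    if Q < 1:
        raise ValueError("Q must be >= 1")
    if params.N / Q < 50:
        raise ValueError(f"N/Q = {params.N / Q:.0f} < 50; choose a smaller Q")
    burn = None if params.burn_in is None else max(1, round(params.burn_in / Q))
    return replace(
        params,
        N=int(round(params.N / Q)),
        s=params.s * Q,
        mu=params.mu * Q,
        rec_map=[(a, b, r * Q) for a, b, r in params.rec_map],
        t_intro=max(1, round(params.t_intro / Q)),
        burn_in=burn,
        rescale_q=params.rescale_q * Q,
    )


def desk_preset(
    s: float = 0.01, t_intro: int = 16_030, Q: float = 120.0, L: int = 2_000_000
) -> SimParams:
    """Desk-scale preset: Q-rescaled (N/Q = 500) and chromosome shrunk to L.

    Coordinates (pericentromere span, selected site, analysis windows) shrink
    with the chromosome so map proportions are preserved; per-bp rates are
    rescaled by Q only, keeping per-site theta and rho at their Q-rescaled
    values.
    """
    p = rescale(full_scale_params(s=s, t_intro=t_intro), Q)
    lam = FULL_LENGTH / L

    def sc(x: float) -> int:
        return max(1, int(round(x / lam)))

    peri = (sc(PERI_SPAN[0]), sc(PERI_SPAN[1]))
    rec_map = [
        (1, peri[0] - 1, ARM_RATE * Q),
        (peri[0], peri[1], PERI_RATE * Q),
        (peri[1] + 1, L, ARM_RATE * Q),
    ]
    return replace(
        p,
        L=L,
        rec_map=rec_map,
        sel_pos=sc(SEL_POS),
        pi_window=sc(200_000),
        pi_stride=sc(25_000),
    )


def footprint_preset(
    s: float = 0.001,
    t_intro: int = 16_030,
    L: int = 200_000,
    Q: float = 120.0,
) -> SimParams:
    """Desk chromosome designed for footprint-measurement experiments.

    A uniform (Q-rescaled arm-rate) recombination map with the selected site
    at the centre gives a symmetric, sharply interpretable footprint: under
    95% selfing the effective recombination is reduced by 1 - F ~ 0.095, and
    with this map a Q-rescaled sweep's footprint spans a mid fraction of the
    chromosome instead of engulfing it.  ``s`` and ``t_intro`` are in
    full-scale units and are Q-rescaled here.
    """
    return SimParams(
        N=round(FULL_N / Q),
        L=L,
        rec_map=[(1, L, ARM_RATE * Q)],
        mu=4e-9 * Q,
        sel_pos=L // 2,
        s=s * Q,
        t_intro=max(1, round(t_intro / Q)),
        rescale_q=Q,
        pi_window=10_000,
        pi_stride=1_250,
    )


@dataclass
class HaplotypePopulation:
    """Forward-simulation state.

    ``geno`` is (2N haplotypes x M segregating neutral sites) boolean;
    ``positions`` the (sorted, continuous) site positions; ``sel`` the
    per-haplotype selected-site allele.
    """

    params: SimParams
    positions: np.ndarray
    geno: np.ndarray
    sel: np.ndarray
    generation: int = 0
    trajectory: list[float] = field(default_factory=list)

    @property
    def n_haplotypes(self) -> int:
        return self.geno.shape[0]

    @property
    def sel_frequency(self) -> float:
        return float(self.sel.mean()) if len(self.sel) else 0.0

    def sample_haplotypes(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """One random haplotype from each of ``size`` distinct individuals."""
        N = self.params.N
        if size > N:
            raise ValueError("sample size exceeds number of individuals")
        ind = rng.choice(N, size=size, replace=False)
        hap = rng.integers(0, 2, size=size)
        return self.geno[2 * ind + hap]


@dataclass
class SweepExtent:
    """Measured physical extent of a sweep footprint."""

    left: float
    right: float
    method: str
    detected: bool = True

    @property
    def size(self) -> float:
        return self.right - self.left


@njit(cache=True)
def _transmit_kernel(geno, positions, parent, phase, bp_flat, bp_offs, out):
    """Copy each gamete from its parent's two haplotypes, switching at the
    (sorted) crossover breakpoints."""
    twoN, M = out.shape
    for g in range(twoN):
        hap = phase[g]
        src = 2 * parent[g] + hap
        lo = 0
        for k in range(bp_offs[g], bp_offs[g + 1]):
            hi = np.searchsorted(positions, bp_flat[k])
            if hi > lo:
                out[g, lo:hi] = geno[src, lo:hi]
                lo = hi
            hap = 1 - hap
            src = 2 * parent[g] + hap
        out[g, lo:M] = geno[src, lo:M]


@njit(cache=True)
def _mutate_kernel(geno, src, new_gam, new_col, out):
    """Gather existing columns (src >= 0) and scatter new singleton
    mutation columns into ``out`` (row-contiguous writes)."""
    twoN, Mout = out.shape
    for g in range(twoN):
        for k in range(Mout):
            s = src[k]
            out[g, k] = geno[g, s] if s >= 0 else False
    for j in range(len(new_gam)):
        out[new_gam[j], new_col[j]] = True


class _Engine:
    """Vectorized one-generation update of the whole population."""

    def __init__(self, params: SimParams, rng: np.random.Generator):
        self.p = params
        self.rng = rng
        starts = np.array([a for a, _, _ in params.rec_map], dtype=float)
        ends = np.array([b for _, b, _ in params.rec_map], dtype=float)
        rates = np.array([r for _, _, r in params.rec_map], dtype=float)
        seg_map = (ends - starts + 1) * rates
        self.total_map = float(seg_map.sum())  # E[crossovers per gamete]
        self.cum_map = np.concatenate([[0.0], np.cumsum(seg_map)])
        self.seg_starts = starts
        self.seg_rates = rates

    def _sample_breakpoints(self, n: int) -> np.ndarray:
        """n crossover positions from the map density (continuous bp)."""
        u = self.rng.random(n) * self.total_map
        i = np.clip(np.searchsorted(self.cum_map, u, side="right") - 1, 0, len(self.seg_rates) - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            within = np.where(
                self.seg_rates[i] > 0, (u - self.cum_map[i]) / self.seg_rates[i], 0.0
            )
        return self.seg_starts[i] + within

    def step(self, positions, geno, sel, select: bool):
        p = self.p
        N, twoN = p.N, 2 * p.N
        s_coef = p.s if select else 0.0
        wmax = max(1.0, 1.0 + s_coef, 1.0 + p.h * s_coef)
        rng = self.rng

        parent_parts, phase_parts, sel_parts, bp_parts = [], [], [], []
        got = 0
        while got < N:
            batch = max(32, int((N - got) * wmax * 1.15) + 8)
            p1 = rng.integers(0, N, batch)
            selfed = rng.random(batch) < p.selfing
            p2 = np.where(selfed, p1, rng.integers(0, N, batch))
            parents = np.stack([p1, p2], axis=1)  # (batch, 2)
            phases = rng.integers(0, 2, (batch, 2))
            n_x = rng.poisson(self.total_map, (batch, 2))
            total_x = int(n_x.sum())
            all_bps = self._sample_breakpoints(total_x) if total_x else np.empty(0)
            flat_nx = n_x.ravel()
            offs = np.concatenate([[0], np.cumsum(flat_nx)])
            # per-gamete breakpoints, sorted, as an inf-padded matrix
            maxk = int(flat_nx.max()) if total_x else 0
            Bp_all = np.full((2 * batch, maxk), np.inf)
            if total_x:
                gid = np.repeat(np.arange(2 * batch), flat_nx)
                order = np.lexsort((all_bps, gid))
                within = np.arange(total_x) - offs[gid]
                Bp_all[gid, within] = all_bps[order]
                flat_counts = np.bincount(
                    gid[all_bps <= p.sel_pos], minlength=2 * batch
                )
            else:
                flat_counts = np.zeros(2 * batch, dtype=np.int64)
            # transmitted selected allele per gamete: haplotype at sel_pos
            src = (phases + flat_counts.reshape(batch, 2)) % 2
            child_sel = sel[2 * parents + src]  # (batch, 2)
            if select and s_coef != 0.0:
                g_cnt = child_sel.sum(axis=1)
                w = np.where(
                    g_cnt == 2, 1.0 + s_coef, np.where(g_cnt == 1, 1.0 + p.h * s_coef, 1.0)
                )
                accept = rng.random(batch) < w / wmax
            else:
                accept = np.ones(batch, dtype=bool)
            keep = np.flatnonzero(accept)[: N - got]
            gam_idx = np.stack([2 * keep, 2 * keep + 1], axis=1).ravel()
            parent_parts.append(parents[keep].ravel())
            phase_parts.append(phases[keep].ravel())
            sel_parts.append(child_sel[keep].ravel())
            bp_parts.append(Bp_all[gam_idx])
            got += len(keep)
        acc_parent = np.concatenate(parent_parts)
        acc_phase = np.concatenate(phase_parts)
        acc_sel = np.concatenate(sel_parts).astype(bool)
        maxk = max(b.shape[1] for b in bp_parts)
        Bp = np.full((twoN, maxk), np.inf)
        row0 = 0
        for part in bp_parts:
            Bp[row0 : row0 + len(part), : part.shape[1]] = part
            row0 += len(part)

        # neutral transmission for the accepted gametes: parity at a site =
        # phase XOR (number of crossovers to its left), computed by scattering
        # crossover columns and a cumulative XOR along the chromosome
        M = len(positions)
        if M > 0:
            finite = np.isfinite(Bp)
            n_bp = finite.sum(axis=1)
            bp_offs = np.concatenate([[0], np.cumsum(n_bp)]).astype(np.int64)
            bp_flat = Bp[finite]  # row-major: sorted within each gamete
            new_geno = np.empty((twoN, M), dtype=np.bool_)
            _transmit_kernel(
                geno,
                positions,
                acc_parent.astype(np.int64),
                acc_phase.astype(np.int64),
                bp_flat,
                bp_offs,
                new_geno,
            )
        else:
            new_geno = np.empty((twoN, 0), dtype=bool)

        # new neutral mutations (infinite sites, continuous positions)
        n_mut = rng.poisson(p.mu * p.L * twoN)
        if n_mut:
            mpos = np.sort(rng.random(n_mut) * p.L)
            mgam = rng.integers(0, twoN, n_mut)
            ins = np.searchsorted(positions, mpos)
            positions = np.insert(positions, ins, mpos)
            # src[k] = old column index, or -1 for a new mutation column
            Mout = M + n_mut
            src = np.full(Mout, -1, dtype=np.int64)
            new_col = ins + np.arange(n_mut)
            old_mask = np.ones(Mout, dtype=bool)
            old_mask[new_col] = False
            src[old_mask] = np.arange(M)
            merged = np.empty((twoN, Mout), dtype=np.bool_)
            _mutate_kernel(new_geno, src, mgam.astype(np.int64), new_col, merged)
            new_geno = merged

        return positions, new_geno, acc_sel


def _prune_fixed(positions, geno, keep_fixed: bool = False):
    """Drop lost columns, and fixed columns unless ``keep_fixed``.

    The sweep phase keeps fixed-derived sites: alleles dragged to fixation
    by hitchhiking are part of the footprint signal.  The neutral burn-in
    drops them, which makes the burn-in end state the polarization baseline.
    """
    seg = geno.any(axis=0)
    if not keep_fixed:
        seg &= ~geno.all(axis=0)
    return positions[seg], geno[:, seg]


def run_neutral(
    params: SimParams, rng: np.random.Generator, generations: int | None = None
) -> HaplotypePopulation:
    """Neutral forward evolution from an empty population.

    Runs ``generations`` (default: the burn-in, 10*N) generations of
    mutation-drift-recombination under partial selfing, with no selected
    allele present.
    """
    gens = generations if generations is not None else params.effective_burn_in
    eng = _Engine(params, rng)
    twoN = 2 * params.N
    positions = np.empty(0)
    geno = np.empty((twoN, 0), dtype=bool)
    sel = np.zeros(twoN, dtype=bool)
    for g in range(gens):
        positions, geno, sel = eng.step(positions, geno, sel, select=False)
        if (g + 1) % 25 == 0:
            positions, geno = _prune_fixed(positions, geno)
    positions, geno = _prune_fixed(positions, geno)
    return HaplotypePopulation(
        params=params, positions=positions, geno=geno, sel=sel, generation=gens
    )


def run_forward(
    params: SimParams,
    seed: int,
    burn_in_state: HaplotypePopulation | None = None,
    condition: bool = True,
) -> tuple[HaplotypePopulation, np.ndarray, int]:
    """Burn in, introduce the selected allele, and run to the present.

    The selected allele enters as a single copy ``t_intro`` generations
    before present.  With ``condition``, replicates where it is lost or ends
    below ``freq_threshold`` are discarded and the sweep phase is re-run
    with a fresh random substream (the burn-in state is reused across
    retries), up to ``retry_cap`` attempts.

    Returns (final population, selected-allele frequency trajectory, number
    of discarded attempts).  Fully deterministic given (params, seed).
    """
    rng = np.random.default_rng(seed)
    if burn_in_state is None:
        burn_in_state = run_neutral(params, rng)
    base_pos = burn_in_state.positions
    base_geno = burn_in_state.geno
    twoN = 2 * params.N

    n_failed = 0
    for attempt in range(params.retry_cap):
        sub = np.random.default_rng(rng.integers(0, 2**31 - 1))
        eng = _Engine(params, sub)
        positions = base_pos.copy()
        geno = base_geno.copy()
        sel = np.zeros(twoN, dtype=bool)
        sel[int(sub.integers(0, twoN))] = True
        traj = [sel.mean()]
        lost = False
        for g in range(params.t_intro):
            positions, geno, sel = eng.step(positions, geno, sel, select=True)
            traj.append(sel.mean())
            if condition and not sel.any():
                lost = True
                break
            if (g + 1) % 25 == 0:
                positions, geno = _prune_fixed(positions, geno, keep_fixed=True)
        if condition and (lost or traj[-1] < params.freq_threshold):
            n_failed += 1
            continue
        positions, geno = _prune_fixed(positions, geno, keep_fixed=True)
        pop = HaplotypePopulation(
            params=params,
            positions=positions,
            geno=geno,
            sel=sel,
            generation=burn_in_state.generation + params.t_intro,
            trajectory=list(map(float, traj)),
        )
        return pop, np.asarray(traj), n_failed
    raise RuntimeError(
        f"conditioning failed in {params.retry_cap} attempts "
        f"({n_failed} losses/sub-threshold runs); small s often needs many tries"
    )


def to_genotype_matrix(
    pop: HaplotypePopulation,
    sample_size: int = 20,
    rng: np.random.Generator | None = None,
    keep_fixed_derived: bool = False,
):
    """Export a haplotype sample as a GenotypeMatrix (derived-coded).

    Continuous mutation positions are rounded up to integer bp (collisions,
    which are vanishingly rare, keep the first site).  Columns monomorphic
    ancestral in the sample are dropped; fixed-derived columns are kept when
    ``keep_fixed_derived`` (outgroup-polarized scans use them).  Calls are
    0 = ancestral, 1 = derived.
    """
    from .genotype import GenotypeMatrix

    rng = rng if rng is not None else np.random.default_rng(0)
    H = pop.sample_haplotypes(sample_size, rng)
    c = H.sum(axis=0)
    keep = (c > 0) & ((c < H.shape[0]) | keep_fixed_derived)
    H = H[:, keep]
    pos = np.ceil(pop.positions[keep]).astype(np.int64)
    pos = np.maximum(pos, 1)
    uniq = np.concatenate([[True], np.diff(pos) > 0])
    H, pos = H[:, uniq], pos[uniq]
    n_sites = len(pos)
    return GenotypeMatrix(
        sample_ids=[f"hap{i:03d}" for i in range(H.shape[0])],
        chrom=np.array(["sim"] * n_sites, dtype=object),
        pos=pos,
        ref_allele=np.array(["A"] * n_sites, dtype=object),
        alt_allele=np.array(["T"] * n_sites, dtype=object),
        calls=H.astype(np.int8),
    )


# ---------------------------------------------------------------------------
# Diversity profile and sweep-footprint estimators


def pi_profile(
    pop: HaplotypePopulation,
    window: int | None = None,
    stride: int | None = None,
    sample_size: int = 20,
    rng: np.random.Generator | None = None,
) -> list[WindowStat]:
    """Windowed per-bp nucleotide diversity on a haplotype sample.

    Windows default to the (rescale-aware) values carried by the simulation
    parameters.  Monomorphic populations give an all-zero profile.
    """
    p = pop.params
    window = window if window is not None else p.pi_window
    stride = stride if stride is not None else p.pi_stride
    rng = rng if rng is not None else np.random.default_rng(0)
    H = pop.sample_haplotypes(sample_size, rng)
    n = H.shape[0]
    c = H.sum(axis=0)
    terms = 2.0 * c * (n - c) / (n * (n - 1.0))
    out: list[WindowStat] = []
    start = 1
    while start <= p.L:
        end = min(start + window - 1, p.L)
        in_w = (pop.positions >= start - 1) & (pop.positions < end)
        length = end - start + 1
        val = float(terms[in_w].sum() / length)
        out.append(WindowStat("sim", start, end, int(in_w.sum()), length, val))
        start += stride
    return out


def _profile_arrays(profile: list[WindowStat]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    starts = np.array([w.start for w in profile], dtype=float)
    ends = np.array([w.end for w in profile], dtype=float)
    mids = (starts + ends) / 2.0
    vals = np.array([w.value for w in profile], dtype=float)
    return starts, ends, mids, vals


def sweep_extent_windows(
    profile: list[WindowStat],
    selected_pos: float,
    ref_region: tuple[float, float],
) -> SweepExtent:
    """Window-rule footprint: contiguous sub-threshold run around the sweep.

    The threshold is the mean diversity of windows contained in the distant
    reference region; the extent is the maximal contiguous run of windows
    strictly below it that contains the selected site's window; boundaries
    are the outer window edges.  Ties (value equal to the threshold) count
    as not swept.
    """
    starts, ends, mids, vals = _profile_arrays(profile)
    lo, hi = ref_region
    in_ref = (starts >= lo) & (ends <= hi)
    if not in_ref.any():
        in_ref = (mids >= lo) & (mids <= hi)
    if not in_ref.any():
        raise ValueError("reference region contains no windows")
    thr = float(np.nanmean(vals[in_ref]))
    below = vals < thr
    centre = int(np.argmin(np.abs(mids - selected_pos)))
    if not below[centre]:
        return SweepExtent(
            left=selected_pos, right=selected_pos, method="window-rule", detected=False
        )
    i = centre
    while i > 0 and below[i - 1]:
        i -= 1
    j = centre
    while j < len(vals) - 1 and below[j + 1]:
        j += 1
    return SweepExtent(left=float(starts[i]), right=float(ends[j]), method="window-rule")


def _fit_flank_ramp(x: np.ndarray, y: np.ndarray, toward: str) -> tuple[float, float, bool]:
    """Least-squares baseline-ramp(-floor) fit on one flank of the valley.

    The flank is modelled as a flat baseline up to an outer breakpoint b1, a
    linear ramp descending toward the valley until an inner breakpoint b2,
    and flat beyond (the valley floor); (b1, b2) are grid-searched over the
    observed window positions and the two levels solved in closed form.
    ``toward`` = "right" means the valley lies at larger x (left flank).
    Returns (outer breakpoint, SSE, significant), significance from an
    F-test against the flat fit at alpha = 0.05 with the ramp required to
    actually descend toward the valley.
    """
    from scipy.stats import f as f_dist

    n = len(x)
    flat_sse = float(((y - y.mean()) ** 2).sum())
    xs = x if toward == "right" else x[::-1] * -1.0  # valley at large xs
    ys = y if toward == "right" else y[::-1]
    best = (float("nan"), np.inf)
    for i in range(n - 1):
        for j in range(i + 1, n):
            b1, b2 = xs[i], xs[j]
            # weights of (baseline level c, floor level f)
            t = np.clip((xs - b1) / (b2 - b1), 0.0, 1.0)
            X = np.column_stack([1.0 - t, t])
            coef, *_ = np.linalg.lstsq(X, ys, rcond=None)
            c, f = coef
            if f >= c:  # must descend toward the valley
                continue
            sse = float(((ys - X @ coef) ** 2).sum())
            if sse < best[1]:
                best = (float(b1), sse)
    b1, sse = best
    if not math.isfinite(b1):
        return float("nan"), flat_sse, False
    outer = b1 if toward == "right" else -b1
    if flat_sse <= 0:
        return outer, sse, False  # flat noiseless profile: nothing to detect
    dof = n - 3
    if dof <= 0 or sse <= 0:
        return outer, sse, True
    F = ((flat_sse - sse) / 2.0) / (sse / dof)
    significant = F > f_dist.ppf(0.95, 2, dof)
    return outer, sse, significant


def sweep_size_piecewise(
    profile: list[WindowStat], selected_pos: float
) -> SweepExtent:
    """Piecewise-linear-regression footprint estimator.

    On each flank of the selected site the diversity profile is fit with a
    flat baseline, a linear ramp descending toward the valley, and a flat
    floor; the two outer (baseline-side) breakpoints delimit the footprint.
    A flank without a significant ramp puts its boundary at the chromosome
    end (flagged as not detected).
    """
    starts, ends, mids, vals = _profile_arrays(profile)
    left_mask = mids <= selected_pos
    right_mask = mids >= selected_pos
    if left_mask.sum() < 10 or right_mask.sum() < 10:
        raise ValueError("need at least 10 windows on each flank")
    bl, _, sig_l = _fit_flank_ramp(mids[left_mask], vals[left_mask], toward="right")
    br, _, sig_r = _fit_flank_ramp(mids[right_mask], vals[right_mask], toward="left")
    detected = sig_l and sig_r
    left = bl if sig_l else float(starts[0])
    right = br if sig_r else float(ends[-1])
    return SweepExtent(
        left=float(left), right=float(right), method="piecewise-regression", detected=detected
    )


def grid_experiment(
    s_values: tuple[float, ...] = (0.001, 0.01, 0.1),
    t_values: tuple[int, ...] = (16_030, 13_030, 10_030, 7_030, 4_030, 1_030),
    replicates: int = 12,
    preset=desk_preset,
    seed: int = 0,
    sample_size: int = 20,
):
    """Sweep-footprint grid over selection coefficients and onsets.

    For each (s, onset) cell, runs conditioned replicates, measures both
    footprint estimators and returns a tidy pandas DataFrame (one row per
    replicate; failed cells report NaN extents with the retry count).
    The default grid covers selection coefficients 0.001/0.01/0.1 and six
    onsets from 16,030 to 1,030 generations, 12 replicates each.
    """
    import pandas as pd

    master = np.random.default_rng(seed)
    rows = []
    for s in s_values:
        for t in t_values:
            params = preset(s=s, t_intro=t)
            ref = (0.9 * params.L, params.L)
            for rep in range(replicates):
                rep_seed = int(master.integers(0, 2**31 - 1))
                try:
                    pop, traj, n_failed = run_forward(params, seed=rep_seed)
                    prof = pi_profile(
                        pop, sample_size=sample_size, rng=np.random.default_rng(rep_seed)
                    )
                    w = sweep_extent_windows(prof, params.sel_pos, ref)
                    pw = sweep_size_piecewise(prof, params.sel_pos)
                    rows.append(
                        dict(
                            s=s,
                            t_intro=t,
                            rep=rep,
                            seed=rep_seed,
                            final_freq=float(traj[-1]),
                            n_retries=n_failed,
                            extent_windows=w.size if w.detected else 0.0,
                            extent_piecewise=pw.size,
                            piecewise_detected=pw.detected,
                        )
                    )
                except RuntimeError as err:
                    log.warning("cell (s=%g, t=%d) rep %d failed: %s", s, t, rep, err)
                    rows.append(
                        dict(
                            s=s,
                            t_intro=t,
                            rep=rep,
                            seed=rep_seed,
                            final_freq=np.nan,
                            n_retries=params.retry_cap,
                            extent_windows=np.nan,
                            extent_piecewise=np.nan,
                            piecewise_detected=False,
                        )
                    )
    return pd.DataFrame(rows)
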