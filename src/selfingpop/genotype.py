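"""Genotype data model and standard-format I/O.

The panel is a set of highly selfing strains, each contributing a single
haploid genome: genotype calls are coded 0 (reference allele), 1 (alternate
allele) or :data:`MISSING`.  Diploid VCF records are collapsed to this haploid
coding on read (homozygotes map to their allele; residual heterozygotes are
ambiguous under the haploid treatment and default to missing).

Coordinates are 1-based inclusive internally (VCF convention); BED input is
converted on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from cyvcf2 import VCF

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "MaskSet",
    "GeneModel",
    "Variant",
    "VariantSet",
    "read_vcf",
    "write_vcf",
    "read_mask_bed",
    "read_fasta",
    "read_gff3_gene",
    "filter_sites",
    "ld_prune",
    "pairwise_r2",
]

log = logging.getLogger(__name__)

#: Sentinel for an unknown haploid call.
MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP matrix of haploid-coded calls.

    Attributes
    ----------
    sample_ids : list[str]
        Strain identifiers, one per row of ``calls``.
    chrom : ndarray of str
        Chromosome name per site.
    pos : ndarray of int
        1-based position per site, strictly increasing within a chromosome.
    ref_allele, alt_allele : ndarray of str
        Single-base alleles per site.
    calls : ndarray of int8, shape (n_samples, n_sites)
        0 = ref, 1 = alt, ``MISSING`` = unknown.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.pos)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.pos)} sites"
            )
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def take_sites(self, idx) -> "GenotypeMatrix":
        """Return a new matrix restricted to site indices ``idx`` (in order)."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref_allele=self.ref_allele[idx],
            alt_allele=self.alt_allele[idx],
            calls=self.calls[:, idx],
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = list(idx)
        if idx and isinstance(idx[0], str):
            lookup = {s: i for i, s in enumerate(self.sample_ids)}
            idx = [lookup[s] for s in idx]
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            chrom=self.chrom,
            pos=self.pos,
            ref_allele=self.ref_allele,
            alt_allele=self.alt_allele,
            calls=self.calls[idx, :],
        )

    def missing_per_sample(self) -> dict[str, int]:
        counts = (self.calls == MISSING).sum(axis=1)
        return dict(zip(self.sample_ids, (int(c) for c in counts)))

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt count, observed sample size) over non-missing calls."""
        obs = self.calls != MISSING
        alt = (self.calls == 1).sum(axis=0)
        return alt.astype(np.int64), obs.sum(axis=0).astype(np.int64)


class MaskSet:
    """Per-sample masked (unobservable) genomic intervals.

    Intervals are 1-based inclusive internally and normalized to a sorted,
    non-overlapping form per (sample, chromosome).
    """

    def __init__(self, intervals: dict[str, dict[str, np.ndarray]] | None = None):
        # sample -> chrom -> (k, 2) int array of [start, end] inclusive
        self._iv: dict[str, dict[str, np.ndarray]] = {}
        if intervals:
            for sample, chroms in intervals.items():
                for chrom, arr in chroms.items():
                    for start, end in np.atleast_2d(np.asarray(arr, dtype=np.int64)):
                        self.add(sample, chrom, int(start), int(end))

    def add(self, sample: str, chrom: str, start: int, end: int) -> None:
        """Add a 1-based inclusive interval; merged lazily on access."""
        if end < start:
            raise ValueError(f"mask interval end < start: {chrom}:{start}-{end}")
        per = self._iv.setdefault(sample, {})
        arr = per.get(chrom)
        new = np.array([[start, end]], dtype=np.int64)
        per[chrom] = new if arr is None else np.vstack([arr, new])
        per["__dirty__" + chrom] = None  # type: ignore[assignment]

    def intervals(self, sample: str, chrom: str) -> np.ndarray:
        """Sorted, merged intervals for one sample and chromosome, (k, 2)."""
        per = self._iv.get(sample, {})
        arr = per.get(chrom)
        if arr is None:
            return np.empty((0, 2), dtype=np.int64)
        if ("__dirty__" + chrom) in per:
            arr = _merge_intervals(arr)
            per[chrom] = arr
            del per["__dirty__" + chrom]
        return arr

    @property
    def samples(self) -> list[str]:
        return list(self._iv.keys())

    def chroms(self, sample: str) -> list[str]:
        return [c for c in self._iv.get(sample, {}) if not c.startswith("__dirty__")]

    def masked_length(self, sample: str, chrom: str) -> int:
        iv = self.intervals(sample, chrom)
        if len(iv) == 0:
            return 0
        return int((iv[:, 1] - iv[:, 0] + 1).sum())

    def is_masked(self, sample: str, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean per position: does it fall in a masked interval?"""
        pos = np.asarray(pos, dtype=np.int64)
        iv = self.intervals(sample, chrom)
        if len(iv) == 0:
            return np.zeros(pos.shape, dtype=bool)
        i = np.searchsorted(iv[:, 0], pos, side="right") - 1
        ok = i >= 0
        out = np.zeros(pos.shape, dtype=bool)
        out[ok] = pos[ok] <= iv[i[ok], 1]
        return out

    def apply(self, g: GenotypeMatrix) -> GenotypeMatrix:
        """Set calls at masked positions to MISSING (idempotent)."""
        calls = g.calls.copy()
        for si, sample in enumerate(g.sample_ids):
            for chrom in np.unique(g.chrom):
                sel = g.chrom == chrom
                hit = self.is_masked(sample, str(chrom), g.pos[sel])
                cols = np.flatnonzero(sel)[hit]
                calls[si, cols] = MISSING
        return replace(g, calls=calls)

    def union_pair(self, a: str, b: str, chrom: str) -> np.ndarray:
        """Merged union of two samples' masks on one chromosome."""
        iva, ivb = self.intervals(a, chrom), self.intervals(b, chrom)
        both = np.vstack([iva, ivb])
        return _merge_intervals(both) if len(both) else both


def _merge_intervals(arr: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent 1-based inclusive intervals."""
    if len(arr) == 0:
        return arr.reshape(0, 2).astype(np.int64)
    arr = arr[np.argsort(arr[:, 0])]
    out = [list(arr[0])]
    for start, end in arr[1:]:
        if start <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], end)
        else:
            out.append([start, end])
    return np.array(out, dtype=np.int64)


@dataclass
class GeneModel:
    """A single-transcript gene model (1-based inclusive intervals).

    ``exons`` and ``cds`` are ordered 5'->3' on the coding strand; the
    spliced CDS length must be divisible by 3.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        rev = self.strand == "-"
        self.exons = sorted((tuple(e) for e in self.exons), reverse=rev)
        self.cds = sorted((tuple(c) for c in self.cds), reverse=rev)
        cds_len = sum(e - s + 1 for s, e in self.cds)
        if cds_len % 3 != 0:
            raise ValueError(f"spliced CDS length {cds_len} not divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass(frozen=True)
class Variant:
    """A SNP or small indel in genomic coordinates (1-based)."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class VariantSet:
    """Sorted, non-overlapping variants carried by one strain."""

    variants: list[Variant] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.variants = sorted(self.variants, key=lambda v: (v.chrom, v.pos))
        prev_end: dict[str, int] = {}
        for v in self.variants:
            end = v.pos + len(v.ref) - 1
            if v.chrom in prev_end and v.pos <= prev_end[v.chrom]:
                raise ValueError(f"overlapping variants at {v.chrom}:{v.pos}")
            prev_end[v.chrom] = end

    def __iter__(self):
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)


# ---------------------------------------------------------------------------
# Readers / writers


def read_vcf(
    path: str,
    region: str | None = None,
    het_policy: str = "missing",
    skip_multiallelic: bool = True,
) -> tuple[GenotypeMatrix, int]:
    """Read biallelic SNPs from a VCF into a haploid-coded matrix.

    Diploid genotypes collapse 0/0 -> 0, 1/1 -> 1; heterozygotes follow
    ``het_policy`` ("missing", "ref" or "alt").  Sites with more than two
    alleles are skipped (counted) when ``skip_multiallelic`` is set, else an
    error is raised.

    Returns
    -------
    (GenotypeMatrix, int)
        The matrix and the number of skipped multiallelic records.
    """
    if het_policy not in ("missing", "ref", "alt"):
        raise ValueError(f"unknown het_policy {het_policy!r}")
    vcf = VCF(path)
    samples = list(vcf.samples)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_skipped = 0
    last: dict[str, int] = {}
    it = vcf(region) if region else vcf
    for rec in it:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            if skip_multiallelic:
                n_skipped += 1
                continue
            raise ValueError(f"multiallelic/non-SNP record at {rec.CHROM}:{rec.POS}")
        if rec.CHROM in last and rec.POS <= last[rec.CHROM]:
            raise ValueError(f"VCF not sorted at {rec.CHROM}:{rec.POS}")
        last[rec.CHROM] = rec.POS
        gt = rec.genotype.array()  # (n, ploidy+1), -1 = missing
        alleles = gt[:, :-1]
        row = np.full(len(samples), MISSING, dtype=np.int8)
        known = np.all(alleles >= 0, axis=1)
        hom_ref = known & np.all(alleles == 0, axis=1)
        hom_alt = known & np.all(alleles == 1, axis=1)
        row[hom_ref] = 0
        row[hom_alt] = 1
        het = known & ~hom_ref & ~hom_alt
        if het_policy == "ref":
            row[het] = 0
        elif het_policy == "alt":
            row[het] = 1
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(row)
    vcf.close()
    calls = (
        np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    if n_skipped:
        log.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    g = GenotypeMatrix(
        sample_ids=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        calls=calls,
    )
    return g, n_skipped


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write the matrix as a minimal haploid VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(g.chrom):
            length = int(g.pos[g.chrom == chrom].max())
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        code = {0: "0", 1: "1", MISSING: "."}
        for j in range(g.n_sites):
            gts = "\t".join(code[int(c)] for c in g.calls[:, j])
            fh.write(
                f"{g.chrom[j]}\t{g.pos[j]}\t.\t{g.ref_allele[j]}\t"
                f"{g.alt_allele[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_mask_bed(path: str, sample: str | None = None, maskset: MaskSet | None = None) -> MaskSet:
    """Read a BED file (0-based half-open) of masked intervals for one sample.

    The intervals are converted to 1-based inclusive and merged.  Pass an
    existing ``maskset`` to accumulate several samples' files.
    """
    ms = maskset if maskset is not None else MaskSet()
    name = sample if sample is not None else path
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: BED end <= start ({line!r})")
            ms.add(name, chrom, start + 1, end)
    return ms


def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into an upper-cased name -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def read_gff3_gene(path: str, gene_id: str | None = None) -> GeneModel:
    """Read one gene model from a GFF3 subset (gene/mRNA/exon/CDS lines)."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = f[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID", "gene")
                genes[gid] = {
                    "chrom": chrom,
                    "strand": strand,
                    "span": (int(start), int(end)),
                    "exons": [],
                    "cds": [],
                }
            elif ftype in ("exon", "CDS"):
                parent = attr.get("Parent", "")
                target = None
                for gid in genes:
                    if gid in parent or parent.startswith(gid):
                        target = gid
                        break
                if target is None and genes:
                    target = next(iter(genes))
                if target is None:
                    continue
                key = "exons" if ftype == "exon" else "cds"
                genes[target][key].append((int(start), int(end)))
    if not genes:
        raise ValueError(f"no gene feature found in {path}")
    gid = gene_id if gene_id is not None else next(iter(genes))
    if gid not in genes:
        raise KeyError(f"gene {gid!r} not in {path}")
    rec = genes[gid]
    return GeneModel(
        gene_id=gid,
        chrom=rec["chrom"],
        strand=rec["strand"],
        exons=rec["exons"],
        cds=rec["cds"],
        span=rec["span"],
    )


# ---------------------------------------------------------------------------
# Matrix-level filters


def filter_sites(
    g: GenotypeMatrix, max_missing_frac: float = 0.2, min_maf: float = 0.05
) -> GenotypeMatrix:
    """Drop sites with too much missingness or too low minor allele frequency.

    A site passes if missing fraction <= ``max_missing_frac`` and minor
    allele frequency (over observed calls) > ``min_maf`` when ``min_maf`` > 0,
    or MAF >= 0 otherwise.  Site order is preserved.
    """
    if not (0 <= max_missing_frac <= 1):
        raise ValueError("max_missing_frac must be in [0, 1]")
    if not (0 <= min_maf <= 0.5):
        raise ValueError("min_maf must be in [0, 0.5]")
    miss = (g.calls == MISSING).mean(axis=0)
    alt, n_obs = g.allele_counts()
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_obs > 0, alt / np.maximum(n_obs, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    keep = (miss <= max_missing_frac) & (maf > min_maf) & (n_obs > 0)
    if not keep.any():
        warnings.warn("filter_sites removed every site", stacklevel=2)
    return g.take_sites(np.flatnonzero(keep))


def pairwise_r2(calls: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between haploid site columns.

    ``calls`` is (samples, sites) with MISSING allowed; each pair uses
    pairwise-complete observations.  Monomorphic columns give r^2 = 0 by
    convention (no linkage information).
    """
    n_sites = calls.shape[1]
    out = np.zeros((n_sites, n_sites))
    obs = calls != MISSING
    x = calls.astype(float)
    for i in range(n_sites):
        out[i, i] = 1.0
        for j in range(i + 1, n_sites):
            m = obs[:, i] & obs[:, j]
            if m.sum() < 2:
                continue
            xi, xj = x[m, i], x[m, j]
            vi, vj = xi.var(), xj.var()
            if vi == 0 or vj == 0:
                continue
            c = np.corrcoef(xi, xj)[0, 1]
            out[i, j] = out[j, i] = c * c
    return out


def ld_prune(
    g: GenotypeMatrix,
    window_sites: int = 50,
    step_sites: int = 5,
    r2_max: float = 0.2,
) -> list[int]:
    """Greedy within-window LD pruning; returns retained site indices.

    Sliding windows of ``window_sites`` SNPs advance by ``step_sites``.  In
    each window, any retained pair with r^2 > ``r2_max`` loses one member:
    the SNP with more missing calls, ties broken by removing the later
    position (deterministic).
    """
    if not (window_sites >= step_sites >= 1):
        raise ValueError("require window_sites >= step_sites >= 1")
    n = g.n_sites
    removed = np.zeros(n, dtype=bool)
    n_missing = (g.calls == MISSING).sum(axis=0)
    start = 0
    while True:
        stop = min(start + window_sites, n)
        idx = [i for i in range(start, stop) if not removed[i]]
        # restrict each window to one chromosome run
        idx = [i for i in idx if g.chrom[i] == g.chrom[start]]
        if len(idx) > 1:
            r2 = pairwise_r2(g.calls[:, idx])
            changed = True
            while changed:
                changed = False
                live = [k for k in range(len(idx)) if not removed[idx[k]]]
                for a in range(len(live)):
                    for b in range(a + 1, len(live)):
                        ka, kb = live[a], live[b]
                        if r2[ka, kb] > r2_max:
                            ia, ib = idx[ka], idx[kb]
                            if n_missing[ia] > n_missing[ib]:
                                removed[ia] = True
                            elif n_missing[ib] > n_missing[ia]:
                                removed[ib] = True
                            else:
                                removed[max(ia, ib)] = True
                            changed = True
                            break
                    if changed:
                        break
        if stop >= n:
            break
        start += step_sites
    return [i for i in range(n) if not removed[i]]
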