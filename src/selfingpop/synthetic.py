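"""Synthetic data generators with known ground truth.

Every analysis stage in this package is testable without downloads: the
generators here emulate (a) multi-population structured genotype panels with
a target FST under the Balding-Nichols model, (b) a panel containing a
deeply diverged ("relict") subgroup that makes the pairwise-distance
distribution bimodal, (c) per-sample accessibility masks, and (d) a toy
three-exon gene with a designed set of truncating and non-truncating
variants.  All generators are bit-reproducible from (config, seed), and each
fixture can be written in the standard format its consumer reads
(VCF/BED/FASTA/GFF3/TSV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .genotype import (
    MISSING,
    GeneModel,
    GenotypeMatrix,
    MaskSet,
    Variant,
    VariantSet,
)

__all__ = [
    "SyntheticConfig",
    "balding_nichols_panel",
    "relict_panel",
    "mask_fixture",
    "write_mask_bed",
    "gene_fixture",
    "write_gene_fixture",
]


@dataclass
class SyntheticConfig:
    """Shared configuration of the genotype-panel generators."""

    pop_sizes: tuple[int, ...] = (50, 50)
    fst: float = 0.1
    n_sites: int = 5000
    chrom_length: int = 1_000_000
    missing_rate: float = 0.0
    mask_density: float = 0.0
    seed: int = 0
    chrom: str = "chr1"
    # ancestral allele frequencies bounded away from 0/1 so small panels do
    # not produce empty classes
    freq_bounds: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        if not (0 <= self.fst < 1):
            raise ValueError("fst must be in [0, 1)")
        if any(s < 2 for s in self.pop_sizes):
            raise ValueError("each population needs >= 2 samples")
        if not (0 <= self.mask_density < 1):
            raise ValueError("mask density must be in [0, 1)")


def _site_positions(rng: np.random.Generator, n_sites: int, length: int) -> np.ndarray:
    pos = rng.choice(np.arange(1, length + 1), size=n_sites, replace=False)
    return np.sort(pos)


def _as_matrix(cfg: SyntheticConfig, calls: np.ndarray, sample_ids: list[str], pos: np.ndarray) -> GenotypeMatrix:
    n_sites = calls.shape[1]
    bases = np.array(list("ACGT"))
    rng = np.random.default_rng(cfg.seed + 1)
    ref_idx = rng.integers(0, 4, n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, n_sites)) % 4
    return GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.array([cfg.chrom] * n_sites, dtype=object),
        pos=pos,
        ref_allele=bases[ref_idx].astype(object),
        alt_allele=bases[alt_idx].astype(object),
        calls=calls,
    )


def balding_nichols_panel(cfg: SyntheticConfig) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Structured haploid panel with a target FST (Balding-Nichols model).

    Per site, an ancestral frequency p ~ Uniform over ``freq_bounds``; each
    population draws its own frequency p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F)
    (so var(p_k | p) = F p (1-p)); haploid alleles are Bernoulli(p_k), and
    missingness is applied i.i.d.  F = 0 collapses to p_k = p exactly.

    Returns the matrix and sample -> population labels ("pop0", "pop1", ...).
    """
    rng = np.random.default_rng(cfg.seed)
    n_pops = len(cfg.pop_sizes)
    F = cfg.fst
    p = rng.uniform(*cfg.freq_bounds, cfg.n_sites)
    rows, ids, labels = [], [], {}
    for k, size in enumerate(cfg.pop_sizes):
        if F == 0:
            pk = p
        else:
            a = p * (1 - F) / F
            b = (1 - p) * (1 - F) / F
            pk = rng.beta(a, b)
        draws = (rng.random((size, cfg.n_sites)) < pk).astype(np.int8)
        rows.append(draws)
        for i in range(size):
            sid = f"pop{k}_s{i:03d}"
            ids.append(sid)
            labels[sid] = f"pop{k}"
    calls = np.vstack(rows)
    if cfg.missing_rate > 0:
        miss = rng.random(calls.shape) < cfg.missing_rate
        calls[miss] = MISSING
    pos = _site_positions(np.random.default_rng(cfg.seed + 2), cfg.n_sites, cfg.chrom_length)
    return _as_matrix(cfg, calls, ids, pos), labels


def relict_panel(
    cfg: SyntheticConfig | None = None,
    group_sizes: tuple[int, int, int] = (20, 20, 10),
    within_pgd: float = 0.004,
    relict_pgd: float = 0.008,
) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Panel with a deeply diverged subgroup: bimodal distance distribution.

    Two ordinary groups share a founder haplotype; the relict group's
    founder differs at a calibrated fraction of sites so that pairs
    involving a relict strain sit around ``relict_pgd`` while all other
    pairs sit around ``within_pgd`` (defaults mimic modes at 0.4% and
    0.8% of sites).  Collapsing ``relict_pgd`` to ``within_pgd`` collapses
    the distribution to a single mode.
    """
    cfg = cfg or SyntheticConfig(n_sites=20_000, seed=0)
    if relict_pgd < within_pgd:
        raise ValueError("relict_pgd must be >= within_pgd")
    rng = np.random.default_rng(cfg.seed)
    n_sites = cfg.n_sites
    e = within_pgd / 2.0  # private-mutation rate; same-group pairs ~ 2e
    delta = relict_pgd - within_pgd  # founder divergence of the relict group
    founder_main = np.zeros(n_sites, dtype=np.int8)
    # exact divergent-site count keeps the between-group mode on target
    founder_relict = np.zeros(n_sites, dtype=np.int8)
    n_div = int(round(delta * n_sites))
    founder_relict[rng.choice(n_sites, n_div, replace=False)] = 1
    rows, ids, labels = [], [], {}
    names = ("grpA", "grpB", "relict")
    founders = (founder_main, founder_main, founder_relict)
    for name, size, founder in zip(names, group_sizes, founders):
        for i in range(size):
            flips = rng.random(n_sites) < e
            hap = founder ^ flips.astype(np.int8)
            sid = f"{name}_s{i:03d}"
            rows.append(hap)
            ids.append(sid)
            labels[sid] = name
    calls = np.vstack(rows).astype(np.int8)
    pos = _site_positions(np.random.default_rng(cfg.seed + 2), n_sites, max(cfg.chrom_length, 2 * n_sites))
    cfg2 = SyntheticConfig(
        pop_sizes=group_sizes,
        fst=0.0,
        n_sites=n_sites,
        chrom_length=max(cfg.chrom_length, 2 * n_sites),
        seed=cfg.seed,
        chrom=cfg.chrom,
    )
    return _as_matrix(cfg2, calls, ids, pos), labels


def mask_fixture(
    cfg: SyntheticConfig, sample_ids: list[str], interval_length: int | None = None
) -> MaskSet:
    """Random per-sample masks totalling ~``mask_density`` of the chromosome.

    Intervals of roughly ``interval_length`` bp (default: 1% of the
    chromosome) are placed uniformly (merged when they collide) until the
    requested masked fraction is reached.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    ms = MaskSet()
    L = cfg.chrom_length
    iv_len = interval_length or max(1, L // 100)
    for s in sample_ids:
        ms._iv.setdefault(s, {})  # samples with empty masks still registered
        if cfg.mask_density == 0:
            continue
        target = cfg.mask_density * L
        while ms.masked_length(s, cfg.chrom) < target:
            start = int(rng.integers(1, max(2, L - iv_len)))
            ms.add(s, cfg.chrom, start, min(start + iv_len - 1, L))
    return ms


def write_mask_bed(ms: MaskSet, sample: str, chrom: str, path: str) -> None:
    """Write one sample's mask as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for start, end in ms.intervals(sample, chrom):
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


# ---------------------------------------------------------------------------
# Toy gene fixture

# Designed 200-codon CDS (599 of 600 bp shown as codons):
#   codon 1        ATG
#   codons 2-39    TCA (Ser; a C->G SNP makes TGA, C->A makes TAA)
#   codons 40-42   ATA (Ile; +1 frame reads TAA -> frameshift stop)
#   codons 43-45   AAT (Asn; +2 frame reads TAA -> frameshift stop)
#   codons 46-181  TCA
#   codon 182      GGA (Gly; G->T makes TGA: stop leaving a 181-aa product,
#                   91% of the 199-aa reference -> functional boundary)
#   codons 183-199 TCA
#   codon 200      TAA stop
_CDS = (
    "ATG" + "TCA" * 38 + "ATA" * 3 + "AAT" * 3 + "TCA" * 136 + "GGA" + "TCA" * 17 + "TAA"
)
assert len(_CDS) == 600

#: genomic layout (plus strand): 5'UTR 101-200, exon1 101-400 (CDS 201-400),
#: intron1 401-500, exon2 501-800 (all CDS), intron2 801-900,
#: exon3 901-1300 (CDS 901-1000, 3'UTR 1001-1300)
_GENE_SPAN = (101, 1300)
_EXONS = [(101, 400), (501, 800), (901, 1300)]
_CDS_IV = [(201, 400), (501, 800), (901, 1000)]
_CHROM_LEN = 2000


def _build_plus_chromosome(rng: np.random.Generator) -> str:
    bases = "ACGT"
    seq = list(rng.choice(list(bases), _CHROM_LEN))
    # CDS pieces
    cds_parts = [_CDS[:200], _CDS[200:500], _CDS[500:600]]
    for (s, e), part in zip(_CDS_IV, cds_parts):
        seq[s - 1 : e] = list(part)
    # canonical splice dinucleotides GT...AG
    for istart, iend in ((401, 500), (801, 900)):
        seq[istart - 1 : istart + 1] = ["G", "T"]
        seq[iend - 2 : iend] = ["A", "G"]
    # keep UTRs free of accidental ATG before the start codon (tidiness only)
    return "".join(seq)


def _snp(chrom_seq: str, pos: int, alt: str, chrom: str = "chr1") -> Variant:
    return Variant(chrom=chrom, pos=pos, ref=chrom_seq[pos - 1], alt=alt)


def _deletion(chrom_seq: str, anchor: int, n_del: int, chrom: str = "chr1") -> Variant:
    ref = chrom_seq[anchor - 1 : anchor + n_del]
    return Variant(chrom=chrom, pos=anchor, ref=ref, alt=ref[0])


def gene_fixture(seed: int = 0, strand: str = "+"):
    """Toy gene + per-strain variants with a designed truth table.

    Returns (chromosome sequence, GeneModel, strain -> VariantSet,
    truth table strain -> dict(classification, cause)).  Strains cover: no
    variants, a synonymous SNP, a premature stop, a start-codon SNP, a
    splice-site SNP, a frameshift deletion (truncating via its downstream
    stop), and a late stop leaving a 91%-length (functional) protein.

    ``strand="-"`` mirrors the whole construction onto the reverse strand;
    the designed protein products are identical.
    """
    rng = np.random.default_rng(seed)
    chrom_seq = _build_plus_chromosome(rng)
    gene = GeneModel(
        gene_id="toyFRI",
        chrom="chr1",
        strand="+",
        exons=list(_EXONS),
        cds=list(_CDS_IV),
        span=_GENE_SPAN,
    )
    # CDS coordinate -> genomic (plus strand): 1-200 -> 201-400,
    # 201-500 -> 501-800, 501-600 -> 901-1000
    variants = {
        "ref_strain": [],
        # codon 5, third base (CDS 15 -> genomic 215): TCA -> TCG, still Ser
        "synonymous": [_snp(chrom_seq, 215, "G")],
        # codon 10, second base (CDS 29 -> genomic 229): TCA -> TGA stop
        "stop_early": [_snp(chrom_seq, 229, "G")],
        # start codon first base (genomic 201): ATG -> CTG
        "start_loss": [_snp(chrom_seq, 201, "C")],
        # first intronic base after exon 1 (genomic 401, the G of GT)
        "splice": [_snp(chrom_seq, 401, "A")],
        # 2-bp deletion in codon 20 (CDS 58-60 -> genomic 258-260):
        # shifts the frame; the ATA/AAT motif stops translation soon after
        "frameshift": [_deletion(chrom_seq, 257, 2)],
        # codon 182 first base (CDS 544 -> genomic 944): GGA -> TGA, leaving
        # 181 aa = 91% of the reference -> functional by the strict rule
        "late_stop_91pct": [_snp(chrom_seq, 944, "T")],
        # splice + stop on one haplotype: precedence picks splice_site
        "splice_and_stop": [_snp(chrom_seq, 401, "A"), _snp(chrom_seq, 229, "G")],
    }
    truth = {
        "ref_strain": dict(classification="functional", cause="none"),
        "synonymous": dict(classification="functional", cause="none"),
        "stop_early": dict(classification="truncated", cause="premature_stop"),
        "start_loss": dict(classification="truncated", cause="start_loss"),
        "splice": dict(classification="truncated", cause="splice_site"),
        "frameshift": dict(classification="truncated", cause="premature_stop"),
        "late_stop_91pct": dict(classification="functional", cause="none"),
        "splice_and_stop": dict(classification="truncated", cause="splice_site"),
    }
    if strand == "-":
        L = _CHROM_LEN
        chrom_seq = str(Seq(chrom_seq).reverse_complement())

        def flip_iv(iv):
            return [(L - e + 1, L - s + 1) for s, e in iv]

        gene = GeneModel(
            gene_id="toyFRI",
            chrom="chr1",
            strand="-",
            exons=flip_iv(_EXONS),
            cds=flip_iv(_CDS_IV),
            span=(L - _GENE_SPAN[1] + 1, L - _GENE_SPAN[0] + 1),
        )

        def mirror(v: Variant) -> Variant:
            if len(v.ref) == 1 and len(v.alt) == 1:
                p = L - v.pos + 1
                return Variant(
                    chrom=v.chrom,
                    pos=p,
                    ref=str(Seq(v.ref).reverse_complement()),
                    alt=str(Seq(v.alt).reverse_complement()),
                )
            # left-anchored deletion: old deletes bases pos+1..pos+k; the
            # mirrored deletion removes the reverse-complemented bases with a
            # new left anchor
            k = len(v.ref) - 1
            del_lo, del_hi = v.pos + 1, v.pos + k
            new_lo, new_hi = L - del_hi + 1, L - del_lo + 1
            anchor = new_lo - 1
            ref = chrom_seq[anchor - 1 : new_hi]
            return Variant(chrom=v.chrom, pos=anchor, ref=ref, alt=ref[0])

        variants = {k: [mirror(v) for v in vs] for k, vs in variants.items()}
    elif strand != "+":
        raise ValueError("strand must be '+' or '-'")
    variant_sets = {k: VariantSet(vs) for k, vs in variants.items()}
    return chrom_seq, gene, variant_sets, truth


def write_gene_fixture(out_dir: str, seed: int = 0, strand: str = "+") -> dict[str, str]:
    """Write the gene fixture as FASTA + GFF3 + per-strain variant TSV.

    Returns the mapping of artifact name -> path.
    """
    import os

    chrom_seq, gene, variant_sets, truth = gene_fixture(seed=seed, strand=strand)
    os.makedirs(out_dir, exist_ok=True)
    fa = os.path.join(out_dir, "toy_gene.fa")
    with open(fa, "w") as fh:
        fh.write(f">{gene.chrom}\n")
        for i in range(0, len(chrom_seq), 80):
            fh.write(chrom_seq[i : i + 80] + "\n")
    gff = os.path.join(out_dir, "toy_gene.gff3")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        a, b = gene.span
        fh.write(
            f"{gene.chrom}\ttoy\tgene\t{a}\t{b}\t.\t{gene.strand}\t.\tID={gene.gene_id}\n"
        )
        fh.write(
            f"{gene.chrom}\ttoy\tmRNA\t{a}\t{b}\t.\t{gene.strand}\t.\t"
            f"ID={gene.gene_id}.1;Parent={gene.gene_id}\n"
        )
        for s, e in sorted(gene.exons):
            fh.write(
                f"{gene.chrom}\ttoy\texon\t{s}\t{e}\t.\t{gene.strand}\t.\t"
                f"Parent={gene.gene_id}.1\n"
            )
        for s, e in sorted(gene.cds):
            fh.write(
                f"{gene.chrom}\ttoy\tCDS\t{s}\t{e}\t.\t{gene.strand}\t0\t"
                f"Parent={gene.gene_id}.1\n"
            )
    tsv = os.path.join(out_dir, "toy_gene_variants.tsv")
    with open(tsv, "w") as fh:
        fh.write("strain\tchrom\tpos\tref\talt\n")
        for strain, vs in variant_sets.items():
            for v in vs:
                fh.write(f"{strain}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\n")
    tt = os.path.join(out_dir, "toy_gene_truth.tsv")
    with open(tt, "w") as fh:
        fh.write("strain\tclassification\tcause\n")
        for strain, rec in truth.items():
            fh.write(f"{strain}\t{rec['classification']}\t{rec['cause']}\n")
    return dict(fasta=fa, gff3=gff, variants=tsv, truth=tt)
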