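"""Gene-allele reconstruction and truncation classification.

Each strain's allele of a gene is rebuilt by applying its called variants to
the reference sequence, splicing and translating the (possibly shifted) CDS,
and classifying the product: an allele is *truncated* when a variant hits a
canonical splice site (the 2 intronic bases at an exon-intron boundary),
alters the ATG start codon, or yields a protein more than 10% shorter than
the reference protein (strictly less than 90% of its length; exactly 90% is
functional).  Truncated alleles are named by a species prefix plus the
genomic position of the causal polymorphism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from Bio.Seq import Seq

from .genotype import GeneModel, Variant, VariantSet

__all__ = [
    "AlleleCall",
    "CoordinateMap",
    "apply_variants",
    "translate_allele",
    "classify_allele",
    "call_panel",
    "proportion_summary",
    "concordance_rate",
]

log = logging.getLogger(__name__)

CAUSES = ("premature_stop", "start_loss", "splice_site", "short_protein", "none")


@dataclass
class AlleleCall:
    """Per-strain classification of a gene allele."""

    strain: str
    gene_id: str
    classification: str  # "functional" | "truncated"
    cause: str
    protein_length: int
    stop_pos: int | None = None  # genomic bp of a premature stop, if any
    name: str | None = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if (self.classification == "truncated") != (self.cause != "none"):
            raise ValueError("class is truncated iff cause != none")
        if (self.classification == "truncated") != (self.name is not None):
            raise ValueError("truncated alleles (and only those) carry a name")


class CoordinateMap:
    """Old (genomic) <-> new (modified span) coordinate bookkeeping.

    ``old_to_new`` returns the 0-based index in the modified span sequence of
    a genomic position, or None when that base was deleted.
    """

    def __init__(self, span_start: int, old2new: np.ndarray, new2old: np.ndarray):
        self.span_start = span_start
        self._old2new = old2new  # per old base in span, new index or -1
        self._new2old = new2old  # per new base, old genomic pos or -1 (inserted)

    def old_to_new(self, pos: int) -> int | None:
        i = pos - self.span_start
        if i < 0 or i >= len(self._old2new):
            raise IndexError(f"position {pos} outside the gene span")
        v = int(self._old2new[i])
        return None if v < 0 else v

    def new_to_old(self, idx: int) -> int | None:
        """Genomic position of a new-span base (nearest upstream mapped base
        for inserted sequence)."""
        v = int(self._new2old[idx])
        if v >= 0:
            return v
        left = self._new2old[: idx + 1]
        mapped = left[left >= 0]
        return int(mapped[-1]) if len(mapped) else None


def apply_variants(
    ref_seq: str, gene: GeneModel, variants: VariantSet
) -> tuple[str, CoordinateMap]:
    """Apply a strain's variants to the reference gene span.

    ``ref_seq`` is the full chromosome sequence the gene lies on.  Variants
    are applied left to right with cumulative offset bookkeeping; each
    variant's ref field must match the reference (error naming the position
    otherwise).  Returns the modified span sequence (genomic plus-strand
    orientation) and the coordinate map.
    """
    a, b = gene.span
    for v in variants:
        if v.chrom != gene.chrom:
            raise ValueError(f"variant on {v.chrom}, gene on {gene.chrom}")
        if not (a <= v.pos <= b):
            raise ValueError(f"variant at {v.pos} outside gene span {a}-{b}")
        obs = ref_seq[v.pos - 1 : v.pos - 1 + len(v.ref)].upper()
        if obs != v.ref.upper():
            raise ValueError(
                f"ref mismatch at {v.chrom}:{v.pos}: expected {v.ref!r}, found {obs!r}"
            )
    span_len = b - a + 1
    old2new = np.full(span_len, -1, dtype=np.int64)
    parts: list[str] = []
    new2old_parts: list[np.ndarray] = []
    cur = a
    new_len = 0
    for v in variants:
        # untouched stretch before the variant
        if v.pos > cur:
            seg = ref_seq[cur - 1 : v.pos - 1]
            parts.append(seg)
            old2new[cur - a : v.pos - a] = np.arange(new_len, new_len + len(seg))
            new2old_parts.append(np.arange(cur, v.pos))
            new_len += len(seg)
        lr, la = len(v.ref), len(v.alt)
        parts.append(v.alt)
        shared = min(lr, la)
        old2new[v.pos - a : v.pos - a + shared] = np.arange(new_len, new_len + shared)
        seg_map = np.full(la, -1, dtype=np.int64)
        seg_map[:shared] = np.arange(v.pos, v.pos + shared)
        new2old_parts.append(seg_map)
        new_len += la
        cur = v.pos + lr
    if cur <= b:
        seg = ref_seq[cur - 1 : b]
        parts.append(seg)
        old2new[cur - a : b - a + 1] = np.arange(new_len, new_len + len(seg))
        new2old_parts.append(np.arange(cur, b + 1))
        new_len += len(seg)
    new2old = (
        np.concatenate(new2old_parts) if new2old_parts else np.empty(0, dtype=np.int64)
    )
    return "".join(parts), CoordinateMap(a, old2new, new2old)


def _spliced_cds(
    allele_seq: str, gene: GeneModel, cmap: CoordinateMap
) -> tuple[str, list[int], bool]:
    """Extract the (possibly shifted) spliced CDS from the modified span.

    Returns (cds sequence in transcript orientation, new-span indices of its
    bases in transcript order, start_mappable flag).  Intervals whose edges
    were deleted shrink inward; insertions inside an interval are included.
    """
    pieces: list[tuple[int, int]] = []  # new-span [lo, hi] inclusive, genomic order
    for s, e in sorted(gene.cds):
        idx = [cmap.old_to_new(p) for p in range(s, e + 1)]
        mapped = [i for i in idx if i is not None]
        if not mapped:
            continue
        pieces.append((min(mapped), max(mapped)))
    seq = "".join(allele_seq[lo : hi + 1] for lo, hi in pieces)
    indices = [i for lo, hi in pieces for i in range(lo, hi + 1)]
    # is the annotated CDS start still present?
    first = sorted(gene.cds)[0] if gene.strand == "+" else sorted(gene.cds)[-1]
    start_base = first[0] if gene.strand == "+" else first[1]
    start_mappable = cmap.old_to_new(start_base) is not None
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
        indices = indices[::-1]
    return seq, indices, start_mappable


def translate_allele(
    allele_seq: str, gene: GeneModel, cmap: CoordinateMap
) -> tuple[str, int | None]:
    """Translate the spliced CDS of a modified allele.

    Translation uses the standard code and stops at the first stop codon.
    Returns (protein, genomic position of the premature stop codon's first
    base, or None when translation runs to the annotated end).
    """
    cds, indices, start_ok = _spliced_cds(allele_seq, gene, cmap)
    if not start_ok or len(cds) < 3:
        return "", None
    usable = len(cds) - len(cds) % 3
    prot_full = str(Seq(cds[:usable]).translate())
    stop_at = prot_full.find("*")
    if stop_at == -1:
        return prot_full, None
    protein = prot_full[:stop_at]
    if stop_at == usable // 3 - 1:
        return protein, None  # the annotated terminal stop, not premature
    stop_nt = 3 * stop_at  # transcript offset of the stop codon's first base
    stop_genomic = cmap.new_to_old(indices[stop_nt]) if stop_nt < len(indices) else None
    return protein, stop_genomic


def _splice_positions(gene: GeneModel) -> set[int]:
    """Genomic positions of the 2 intronic bases at each exon-intron boundary."""
    exons = sorted(gene.exons)
    out: set[int] = set()
    for (s1, e1), (s2, e2) in zip(exons[:-1], exons[1:]):
        out.update(range(e1 + 1, min(e1 + 2, s2 - 1) + 1))
        out.update(range(max(s2 - 2, e1 + 1), s2))
    return out


def _start_codon_span(gene: GeneModel) -> tuple[int, int]:
    cds = sorted(gene.cds)
    if gene.strand == "+":
        s = cds[0][0]
        return s, s + 2
    e = cds[-1][1]
    return e - 2, e


def _variant_span(v: Variant) -> tuple[int, int]:
    return v.pos, v.pos + max(len(v.ref) - 1, 0)


def _overlaps(span: tuple[int, int], positions) -> bool:
    lo, hi = span
    return any(lo <= p <= hi for p in positions)


def classify_allele(
    ref_seq: str,
    gene: GeneModel,
    variants: VariantSet,
    strain: str = "",
    species_prefix: str = "ch",
    length_fraction: float = 0.90,
    low_confidence: bool = False,
) -> AlleleCall:
    """Classify one strain's allele as functional or truncated.

    Truncation rules, with cause precedence start_loss > splice_site >
    premature_stop / short_protein:

    * start_loss — a variant alters (or a deletion removes) the ATG;
    * splice_site — a variant hits the 2 intronic bases flanking an exon;
    * premature_stop / short_protein — the translated protein is strictly
      shorter than ``length_fraction`` (default 90%) of the reference
      protein; a protein of exactly 90% length stays functional.

    Truncated alleles are named ``<prefix><genomic position of the causal
    polymorphism>``.
    """
    ref_span, ref_map = apply_variants(ref_seq, gene, VariantSet([]))
    ref_protein, _ = translate_allele(ref_span, gene, ref_map)
    allele_seq, cmap = apply_variants(ref_seq, gene, variants)
    protein, stop_pos = translate_allele(allele_seq, gene, cmap)

    start_span = _start_codon_span(gene)
    splice_pos = _splice_positions(gene)

    start_hits = [v for v in variants if _overlaps(_variant_span(v), range(start_span[0], start_span[1] + 1))]
    start_deleted = any(
        cmap.old_to_new(p) is None for p in range(start_span[0], start_span[1] + 1)
    )
    splice_hits = [v for v in variants if _overlaps(_variant_span(v), splice_pos)]

    cause = "none"
    causal: Variant | None = None
    if start_hits or start_deleted:
        cause = "start_loss"
        causal = start_hits[0] if start_hits else (list(variants)[0] if len(variants) else None)
    elif splice_hits:
        cause = "splice_site"
        causal = splice_hits[0]
    elif len(protein) < length_fraction * len(ref_protein):
        cause = "premature_stop" if stop_pos is not None else "short_protein"
        causal = _find_causal(ref_seq, gene, variants, len(ref_protein), length_fraction)

    if cause == "none":
        return AlleleCall(
            strain=strain,
            gene_id=gene.gene_id,
            classification="functional",
            cause="none",
            protein_length=len(protein),
            stop_pos=None,
            name=None,
            low_confidence=low_confidence,
        )
    name_pos = causal.pos if causal is not None else (stop_pos or gene.span[0])
    return AlleleCall(
        strain=strain,
        gene_id=gene.gene_id,
        classification="truncated",
        cause=cause,
        protein_length=len(protein),
        stop_pos=stop_pos,
        name=f"{species_prefix}{name_pos}",
        low_confidence=low_confidence,
    )


def _find_causal(
    ref_seq: str,
    gene: GeneModel,
    variants: VariantSet,
    ref_len: int,
    frac: float,
) -> Variant | None:
    """The 5'-most variant (transcript order) that alone truncates the
    protein; falls back to the 5'-most variant for combination effects."""
    order = sorted(variants, key=lambda v: v.pos, reverse=(gene.strand == "-"))
    for v in order:
        seq, cmap = apply_variants(ref_seq, gene, VariantSet([v]))
        prot, _ = translate_allele(seq, gene, cmap)
        if len(prot) < frac * ref_len:
            return v
    return order[0] if order else None


def call_panel(
    ref_seq: str,
    gene: GeneModel,
    strain_variants: dict[str, VariantSet],
    species_prefix: str = "ch",
    low_confidence: set[str] | None = None,
):
    """Classify every strain's allele and tally distinct truncated alleles.

    Returns (list of AlleleCall, pandas DataFrame of allele frequencies with
    columns name/class/count/frequency).  Strains named in
    ``low_confidence`` (e.g. gene fully masked) are flagged on their call.
    """
    import pandas as pd

    low_confidence = low_confidence or set()
    calls = [
        classify_allele(
            ref_seq,
            gene,
            vs,
            strain=strain,
            species_prefix=species_prefix,
            low_confidence=strain in low_confidence,
        )
        for strain, vs in strain_variants.items()
    ]
    total = len(calls)
    counts: dict[tuple[str, str], int] = {}
    for c in calls:
        key = (c.name or "functional", c.classification)
        counts[key] = counts.get(key, 0) + 1
    freq = pd.DataFrame(
        [
            dict(name=name, classification=cls, count=cnt, frequency=cnt / total)
            for (name, cls), cnt in sorted(counts.items())
        ]
    )
    return calls, freq


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def proportion_summary(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Carrier proportion as a percentage, rounded half-up."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= numerator <= denominator):
        raise ValueError("need 0 <= numerator <= denominator")
    return _round_half_up(100.0 * numerator / denominator, decimals)


def concordance_rate(discordant: int, concordant: int, decimals: int = 2) -> float:
    """Validation error rate: 100 * discordant / (discordant + concordant)."""
    if discordant < 0 or concordant < 0:
        raise ValueError("counts must be non-negative")
    if discordant + concordant == 0:
        raise ValueError("no observations")
    return _round_half_up(100.0 * discordant / (discordant + concordant), decimals)
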