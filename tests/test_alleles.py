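"""Gene-allele reconstruction, translation and truncation classification."""

import numpy as np
import pytest

from selfingpop.alleles import (
    apply_variants,
    call_panel,
    classify_allele,
    concordance_rate,
    proportion_summary,
    translate_allele,
)
from selfingpop.genotype import Variant, VariantSet
from selfingpop.synthetic import gene_fixture


@pytest.fixture(scope="module")
def plus_fixture():
    return gene_fixture(seed=0, strand="+")


class TestApplyVariants:
    def test_no_variants_identity(self, plus_fixture):
        seq, gene, _, _ = plus_fixture
        out, _ = apply_variants(seq, gene, VariantSet([]))
        a, b = gene.span
        assert out == seq[a - 1 : b]

    def test_single_snp(self, plus_fixture):
        seq, gene, _, _ = plus_fixture
        pos = gene.span[0] + 10
        v = Variant("chr1", pos, seq[pos - 1], "T" if seq[pos - 1] != "T" else "G")
        out, _ = apply_variants(seq, gene, VariantSet([v]))
        ref_span = seq[gene.span[0] - 1 : gene.span[1]]
        diffs = [i for i, (x, y) in enumerate(zip(ref_span, out)) if x != y]
        assert diffs == [10]

    def test_deletion_then_snp_matches_string_surgery(self, plus_fixture):
        seq, gene, _, _ = plus_fixture
        a, _ = gene.span
        del_pos = a + 20
        snp_pos = a + 60
        deletion = Variant("chr1", del_pos, seq[del_pos - 1 : del_pos + 2], seq[del_pos - 1])
        snp = Variant("chr1", snp_pos, seq[snp_pos - 1], "A" if seq[snp_pos - 1] != "A" else "C")
        out, cmap = apply_variants(seq, gene, VariantSet([deletion, snp]))
        # naive independent rebuild by string surgery (right to left)
        span = list(seq[gene.span[0] - 1 : gene.span[1]])
        span[snp_pos - a] = snp.alt
        del span[del_pos - a + 1 : del_pos - a + 3]
        assert out == "".join(span)
        # the coordinate map sends the SNP to its post-deletion index
        assert out[cmap.old_to_new(snp_pos)] == snp.alt

    def test_ref_mismatch_raises(self, plus_fixture):
        seq, gene, _, _ = plus_fixture
        pos = gene.span[0] + 5
        wrong = "A" if seq[pos - 1] != "A" else "C"
        with pytest.raises(ValueError, match=str(pos)):
            apply_variants(seq, gene, VariantSet([Variant("chr1", pos, wrong, "G")]))

    def test_overlapping_variants_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            VariantSet(
                [Variant("chr1", 10, "ACG", "A"), Variant("chr1", 11, "C", "T")]
            )

    def test_apply_then_revert_restores_reference(self, plus_fixture):
        seq, gene, vsets, _ = plus_fixture
        a, b = gene.span
        for vs in vsets.values():
            out, _ = apply_variants(seq, gene, vs)
            reverted = [Variant(v.chrom, v.pos, v.alt, v.ref) for v in vs]
            # rebuild a chromosome carrying the variants, then revert on it
            mutated_chrom = seq[: a - 1] + out + seq[b:]
            # positions shift under indels, so revert via left-to-right walk
            back, _ = apply_variants(
                mutated_chrom,
                gene.__class__(
                    gene_id=gene.gene_id,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    exons=gene.exons,
                    cds=gene.cds,
                    span=(a, a + len(out) - 1),
                ),
                VariantSet(_shift_reverts(vs)),
            )
            assert back == seq[a - 1 : b]


def _shift_reverts(vs):
    """Revert variants with cumulative coordinate shifts for indels."""
    out = []
    offset = 0
    for v in sorted(vs, key=lambda v: v.pos):
        out.append(Variant(v.chrom, v.pos + offset, v.alt, v.ref))
        offset += len(v.alt) - len(v.ref)
    return out


class TestTranslateAndClassify:
    def test_reference_protein(self, plus_fixture):
        seq, gene, _, _ = plus_fixture
        out, cmap = apply_variants(seq, gene, VariantSet([]))
        prot, stop = translate_allele(out, gene, cmap)
        assert len(prot) == 199 and prot.startswith("M") and stop is None

    def test_premature_stop_protein_length(self, plus_fixture):
        seq, gene, vsets, _ = plus_fixture
        out, cmap = apply_variants(seq, gene, vsets["stop_early"])
        prot, stop = translate_allele(out, gene, cmap)
        assert len(prot) == 9
        assert stop == 228  # genomic first base of the stop codon (TGA)

    def test_minus_strand_mirror_same_proteins(self):
        seq_p, gene_p, vs_p, _ = gene_fixture(seed=0, strand="+")
        seq_m, gene_m, vs_m, _ = gene_fixture(seed=0, strand="-")
        for strain in vs_p:
            out_p, cm_p = apply_variants(seq_p, gene_p, vs_p[strain])
            out_m, cm_m = apply_variants(seq_m, gene_m, vs_m[strain])
            prot_p, _ = translate_allele(out_p, gene_p, cm_p)
            prot_m, _ = translate_allele(out_m, gene_m, cm_m)
            assert prot_p == prot_m, strain

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_truth_table_reproduced(self, strand):
        seq, gene, vsets, truth = gene_fixture(seed=0, strand=strand)
        for strain, vs in vsets.items():
            call = classify_allele(seq, gene, vs, strain=strain)
            assert call.classification == truth[strain]["classification"], strain
            assert call.cause == truth[strain]["cause"], strain

    def test_91_percent_boundary_is_functional(self, plus_fixture):
        seq, gene, vsets, _ = plus_fixture
        call = classify_allele(seq, gene, vsets["late_stop_91pct"])
        assert call.classification == "functional"
        assert call.protein_length == 181  # 91% of the 199-aa reference

    def test_classification_order_invariant(self, plus_fixture):
        seq, gene, vsets, _ = plus_fixture
        vs = list(vsets["splice_and_stop"])
        c1 = classify_allele(seq, gene, VariantSet(vs))
        c2 = classify_allele(seq, gene, VariantSet(vs[::-1]))
        assert c1 == c2

    def test_truncated_name_within_gene_span(self, plus_fixture):
        seq, gene, vsets, truth = plus_fixture if isinstance(plus_fixture, tuple) else plus_fixture
        a, b = gene.span
        for strain, vs in vsets.items():
            call = classify_allele(seq, gene, vs, strain=strain)
            if call.classification == "truncated":
                pos = int(call.name[2:])
                assert a <= pos <= b


class TestCallPanel:
    def test_uniform_stop_allele_frequency(self, plus_fixture):
        seq, gene, vsets, _ = plus_fixture
        panel = {f"strain{i}": vsets["stop_early"] for i in range(5)}
        calls, freq = call_panel(seq, gene, panel)
        assert all(c.classification == "truncated" for c in calls)
        assert len(freq) == 1 and freq.iloc[0]["frequency"] == 1.0

    def test_distinct_truncating_alleles_counted(self, plus_fixture):
        seq, gene, vsets, truth = plus_fixture
        calls, freq = call_panel(seq, gene, dict(vsets))
        trunc = freq[freq["classification"] == "truncated"]
        expected = {
            c.name
            for c in calls
            if c.classification == "truncated"
        }
        assert set(trunc["name"]) == expected

    def test_precedence_combined_variants(self, plus_fixture):
        seq, gene, vsets, _ = plus_fixture
        call = classify_allele(seq, gene, vsets["splice_and_stop"])
        assert call.cause == "splice_site"

    def test_low_confidence_flagged(self, plus_fixture):
        seq, gene, vsets, _ = plus_fixture
        calls, _ = call_panel(
            seq, gene, {"x": vsets["ref_strain"]}, low_confidence={"x"}
        )
        assert calls[0].low_confidence


class TestSummaries:
    @pytest.mark.parametrize(
        "num,den,dec,expected",
        [(111, 113, 1, 98.2), (112, 280, 0, 40.0), (0, 10, 1, 0.0)],
    )
    def test_proportion_summary(self, num, den, dec, expected):
        assert proportion_summary(num, den, dec) == expected

    @pytest.mark.parametrize(
        "disc,conc,expected", [(6, 2640, 0.23), (0, 100, 0.0), (1, 3, 25.0)]
    )
    def test_concordance_rate(self, disc, conc, expected):
        assert concordance_rate(disc, conc) == expected

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            proportion_summary(1, 0)
        with pytest.raises(ValueError):
            concordance_rate(0, 0)
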