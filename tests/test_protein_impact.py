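"""Genomic-to-CDS projection, codon substitution and translation."""

import numpy as np
import pytest

from cosegscan.protein_impact import (
    TRANSLATE,
    annotate_candidates,
    brute_force_codon_change,
    codon_change,
    project_to_cds,
    three_letter,
    variant_codon_change,
)
from cosegscan.consequence import CandidateVariant
from cosegscan.synthetic_data import all_coding_snvs, random_gene_model
from cosegscan.variant_io import HET, HOM_REF, GeneModel, VariantKey


def _model(strand, segments, cds, gene="G", tx="tx1"):
    return GeneModel(gene=gene, transcript=tx, strand=strand,
                     cds_segments=segments, cds_sequence=cds)


class TestProjectToCds:
    def test_plus_strand_identity(self):
        """+ strand, single segment starting at 101: genomic 150 -> CDS 50."""
        cds = "A" * 49 + "G" + "A" * 52
        m = _model("+", [("1", 101, 202)], cds)
        cds_pos, cref, calt = project_to_cds(VariantKey("1", 150, "G", "C"), m)
        assert (cds_pos, cref, calt) == (50, "G", "C")

    def test_minus_strand_reverse_complement(self):
        """- strand, segment ending at 200, variant at 200 G>C -> CDS 1, C>G."""
        cds = "C" + "A" * 101
        m = _model("-", [("1", 99, 200)], cds)
        cds_pos, cref, calt = project_to_cds(VariantKey("1", 200, "G", "C"), m)
        assert (cds_pos, cref, calt) == (1, "C", "G")

    def test_spliced_plus_strand(self):
        """Two segments (101-130, 201-230): genomic 205 -> CDS 35."""
        cds = "A" * 34 + "G" + "A" * 25
        m = _model("+", [("1", 101, 130), ("1", 201, 230)], cds)
        cds_pos, _, _ = project_to_cds(VariantKey("1", 205, "G", "T"), m)
        assert cds_pos == 35

    def test_noncoding_position_error(self):
        m = _model("+", [("1", 101, 130)], "A" * 30)
        with pytest.raises(ValueError, match="non-coding"):
            project_to_cds(VariantKey("1", 500, "A", "G"), m)

    def test_reference_mismatch_error(self):
        m = _model("+", [("1", 101, 130)], "A" * 30)
        with pytest.raises(ValueError, match="reference mismatch"):
            project_to_cds(VariantKey("1", 110, "C", "G"), m)

    def test_strand_involution(self):
        """Reverse-complementing coding alleles twice recovers the genomic pair."""
        from cosegscan.variant_io import reverse_complement

        for ref, alt in [("G", "C"), ("T", "G"), ("A", "T")]:
            assert reverse_complement(reverse_complement(ref)) == ref
            assert reverse_complement(reverse_complement(alt)) == alt


class TestCodonChange:
    def test_ala_to_gly(self):
        """GCC -> GGC at codon position 2 is Ala > Gly (missense)."""
        m = _model("+", [("1", 1, 6)], "ATGGCC")
        cc = codon_change(5, "C", "G", m)
        assert (cc.ref_codon, cc.alt_codon, cc.kind) == ("GCC", "GGC", "missense")
        assert cc.aa_change == "Ala > Gly"

    def test_leu_to_val(self):
        """CTG -> GTG at codon position 1 is Leu > Val (missense)."""
        m = _model("+", [("1", 1, 6)], "ATGCTG")
        cc = codon_change(4, "C", "G", m)
        assert (cc.ref_codon, cc.alt_codon) == ("CTG", "GTG")
        assert cc.aa_change == "Leu > Val"

    def test_start_loss(self):
        """ATG -> ATA at codon 1 is a start loss (Met > Ile)."""
        m = _model("+", [("1", 1, 6)], "ATGAAA")
        cc = codon_change(3, "G", "A", m)
        assert cc.kind == "start_loss"
        assert (cc.ref_aa, cc.alt_aa) == ("M", "I")

    def test_synonymous(self):
        m = _model("+", [("1", 1, 6)], "ATGCTG")
        cc = codon_change(6, "G", "C", m)  # CTG -> CTC, both Leu
        assert cc.kind == "synonymous"
        assert cc.aa_change == "Leu > Leu"

    def test_stop_gain(self):
        m = _model("+", [("1", 1, 6)], "ATGTGC")
        cc = codon_change(6, "C", "A", m)  # TGC -> TGA
        assert cc.kind == "stop_gain"
        assert three_letter(cc.alt_aa) == "Ter"

    def test_translation_table_total(self):
        """All 64 codons translate; stops map to '*'."""
        assert len(TRANSLATE) == 64
        assert {TRANSLATE[c] for c in ("TAA", "TAG", "TGA")} == {"*"}

    def test_codon_arithmetic(self):
        m = _model("+", [("1", 1, 9)], "ATGGCCAAA")
        cc = codon_change(7, "A", "G", m)
        assert (cc.codon_index, cc.codon_pos) == (3, 1)


class TestOracle:
    def test_agrees_with_full_retranslation(self):
        """Codon arithmetic equals the rebuild-whole-CDS-and-diff oracle for
        every SNV in 200 random toy models (both strands, spliced)."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            model = random_gene_model(rng)
            for variant in all_coding_snvs(model):
                cc = variant_codon_change(variant, model)
                ref_aa, alt_aa = brute_force_codon_change(variant, model)
                assert (cc.ref_aa, cc.alt_aa) == (ref_aa, alt_aa), (
                    f"{variant} on {model.strand} strand"
                )
                assert (cc.kind == "synonymous") == (ref_aa == alt_aa)


class TestAnnotateCandidates:
    def _candidate(self, variant, gene, tx):
        return CandidateVariant(
            variant=variant, genotype_a=HET, genotype_b=HOM_REF,
            effect_class="missense variant", gene=gene, transcript=tx,
        )

    def test_missing_model_leaves_empty(self):
        c = self._candidate(VariantKey("1", 5, "A", "G"), "NOMODEL", "nope")
        out = annotate_candidates([c], {})
        assert out[0].aa_change == ""

    def test_synonymous_toy(self):
        m = _model("+", [("1", 1, 6)], "ATGCTG")
        c = self._candidate(VariantKey("1", 6, "G", "A"), "G", "tx1")  # CTG->CTA
        out = annotate_candidates([c], {"tx1": m})
        assert out[0].aa_change == "Leu > Leu"

    def test_reference_mismatch_names_variant(self):
        m = _model("+", [("1", 1, 6)], "ATGCTG")
        c = self._candidate(VariantKey("1", 6, "C", "A"), "G", "tx1")
        with pytest.raises(ValueError, match="1:6C>A"):
            annotate_candidates([c], {"tx1": m})

    def test_gene_fallback_when_transcript_unknown(self):
        m = _model("+", [("1", 1, 6)], "ATGCTG", gene="G", tx="tx1")
        c = self._candidate(VariantKey("1", 4, "C", "G"), "G", "other-tx")
        out = annotate_candidates([c], {"tx1": m})
        assert out[0].aa_change == "Leu > Val"
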