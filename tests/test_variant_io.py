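"""Format ingestion: VCF, group manifest, annotation TSV, GMT, gene models."""

import numpy as np
import pytest

from cosegscan.variant_io import (
    GT_STR,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    GroupAssignment,
    VariantKey,
    read_annotations,
    read_gene_models,
    read_group_manifest,
    read_term_sets,
    read_vcf,
    write_vcf,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=7>\n"
)


def _write_vcf(tmp_path, body, samples=("S1", "S2")):
    path = tmp_path / "test.vcf"
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    path.write_text(VCF_HEADER + cols + "\n" + body)
    return path


class TestReadVcf:
    def test_nine_sample_snv_record(self, tmp_path):
        """A single record with 6x 0/0 and 3x 0/1 loads into one variant."""
        samples = [f"N{i}" for i in range(6)] + [f"S{i}" for i in range(3)]
        gts = "\t".join(["0/0"] * 6 + ["0/1"] * 3)
        path = _write_vcf(tmp_path, f"7\t22824499\t.\tC\tG\t.\t.\t.\tGT\t{gts}\n", samples)
        m = read_vcf(path)
        assert m.variants == [VariantKey("7", 22824499, "C", "G")]
        assert list(m.calls[0]) == [HOM_REF] * 6 + [HET] * 3

    def test_indels_excluded(self, tmp_path):
        """Non-SNV records are dropped; only the SNV survives."""
        body = (
            "7\t100\t.\tCA\tC\t.\t.\t.\tGT\t0/1\t0/0\n"
            "7\t200\t.\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\n"
        )
        m = read_vcf(_write_vcf(tmp_path, body))
        assert m.variants == [VariantKey("7", 200, "A", "G")]

    def test_multiallelic_split_and_recode(self, tmp_path):
        """A>G,T with GTs 0/1 and 0/2 splits into two biallelic keys; the 0/2
        sample is het for A>T and hom-ref for A>G."""
        body = "7\t200\t.\tA\tG,T\t.\t.\t.\tGT\t0/1\t0/2\n"
        m = read_vcf(_write_vcf(tmp_path, body))
        assert m.variants == [
            VariantKey("7", 200, "A", "G"),
            VariantKey("7", 200, "A", "T"),
        ]
        ag = m.calls[0]
        at = m.calls[1]
        assert list(ag) == [HET, HOM_REF]
        assert list(at) == [HOM_REF, HET]

    def test_phased_separator_normalized(self, tmp_path):
        body = "7\t300\t.\tA\tC\t.\t.\t.\tGT\t1|0\t.\n"
        m = read_vcf(_write_vcf(tmp_path, body))
        assert list(m.calls[0]) == [HET, MISSING]

    def test_duplicate_key_is_error(self, tmp_path):
        body = (
            "7\t400\t.\tA\tC\t.\t.\t.\tGT\t0/0\t0/0\n"
            "7\t400\t.\tA\tC\t.\t.\t.\tGT\t0/1\t0/0\n"
        )
        with pytest.raises(ValueError, match="7:400A>C"):
            read_vcf(_write_vcf(tmp_path, body))

    def test_missing_gt_format_is_error(self, tmp_path):
        path = tmp_path / "nogt.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=7>\n"
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "7\t1\t.\tA\tC\t.\t.\t.\n"
        )
        with pytest.raises(ValueError, match="GT"):
            read_vcf(path)

    def test_round_trip(self, tmp_path, fixture_matrix):
        """Writing a matrix to VCF and re-reading yields an identical matrix."""
        out = tmp_path / "rt.vcf"
        write_vcf(fixture_matrix, out)
        back = read_vcf(out)
        assert back.variants == fixture_matrix.variants
        assert back.samples == fixture_matrix.samples
        assert np.array_equal(back.calls, fixture_matrix.calls)

    def test_all_calls_in_domain(self, fixture_matrix):
        assert set(np.unique(fixture_matrix.calls)) <= {HOM_REF, HET, HOM_ALT, MISSING}


class TestGroupManifest:
    def test_nine_sample_manifest(self, tmp_path):
        samples = [f"SA{i}" for i in range(1, 4)] + [f"NSA{i}" for i in range(1, 7)]
        path = tmp_path / "groups.tsv"
        path.write_text("".join(f"{s}\t{s[:-1]}\n" for s in samples))
        ga = read_group_manifest(path, samples)
        assert ga.groups == {"NSA": 6, "SA": 3}

    def test_extra_sample_dropped(self, tmp_path):
        path = tmp_path / "groups.tsv"
        path.write_text("A\tG1\nB\tG2\nX\tG1\n")
        ga = read_group_manifest(path, ["A", "B"])
        assert "X" not in ga.mapping

    def test_single_group_is_error(self, tmp_path):
        path = tmp_path / "groups.tsv"
        path.write_text("A\tG1\nB\tG1\n")
        with pytest.raises(ValueError, match="two groups"):
            read_group_manifest(path, ["A", "B"])

    def test_uncovered_sample_is_error(self, tmp_path):
        path = tmp_path / "groups.tsv"
        path.write_text("A\tG1\nB\tG2\n")
        with pytest.raises(ValueError, match="missing"):
            read_group_manifest(path, ["A", "B", "C"])


ANN_HEADER = "chrom\tpos\tref\talt\teffect_class\tgene\ttranscript\tstrand\tcds_pos\n"


class TestAnnotations:
    def test_single_row(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(ANN_HEADER + "7\t22824499\tC\tG\tmissense_variant\tSLA-1\ttx1\t+\t44\n")
        df = read_annotations(path)
        assert len(df) == 1 and df.iloc[0]["gene"] == "SLA-1"

    def test_empty_table(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(ANN_HEADER)
        assert len(read_annotations(path)) == 0

    def test_duplicate_key_transcript_is_error(self, tmp_path):
        path = tmp_path / "ann.tsv"
        row = "7\t1\tC\tG\tmissense_variant\tX\ttx1\t+\t\n"
        path.write_text(ANN_HEADER + row + row)
        with pytest.raises(ValueError, match="duplicate"):
            read_annotations(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(ANN_HEADER + "7\t1\tCC\tG\tmissense_variant\tX\ttx1\t+\t\n")
        with pytest.raises(ValueError, match="line 2"):
            read_annotations(path)


class TestTermSets:
    def test_basic_term(self, tmp_path):
        path = tmp_path / "t.gmt"
        path.write_text("antigen_processing\tdesc\tSLA-1\tSLA-2\tSLA-3\tTAP2\n")
        terms = read_term_sets(path)
        assert terms["antigen_processing"] == {"SLA-1", "SLA-2", "SLA-3", "TAP2"}

    def test_duplicate_gene_collapsed_and_uppercased(self, tmp_path):
        path = tmp_path / "t.gmt"
        path.write_text("t1\td\tabc\tABC\txyz\n")
        assert read_term_sets(path)["t1"] == {"ABC", "XYZ"}

    def test_empty_term_dropped_shared_genes_kept(self, tmp_path):
        path = tmp_path / "t.gmt"
        path.write_text("t1\td\tA\tB\nt2\td\n" "t3\td\tA\tC\n")
        terms = read_term_sets(path)
        assert set(terms) == {"t1", "t3"}


class TestGeneModels:
    def test_fixture_models_load(self, fixture_bundle):
        models = read_gene_models(fixture_bundle.gene_models, fixture_bundle.cds_fasta)
        assert {m.gene for m in models.values()} == {"SLA-1", "SLA-2", "SLA-3", "TAP2"}
        for m in models.values():
            assert len(m.cds_sequence) % 3 == 0
            assert m.cds_sequence.startswith("ATG")
            assert sum(e - s + 1 for _, s, e in m.cds_segments) == len(m.cds_sequence)

    def test_minus_strand_segments_in_coding_order(self, fixture_bundle):
        models = read_gene_models(fixture_bundle.gene_models, fixture_bundle.cds_fasta)
        tap2 = models["TAP2-tx1"]
        assert tap2.strand == "-"
        starts = [s for _, s, _ in tap2.cds_segments]
        assert starts == sorted(starts, reverse=True)


class TestDomainTypes:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="7", pos=0, ref="A", alt="C"),
            dict(chrom="7", pos=1, ref="A", alt="A"),
            dict(chrom="7", pos=1, ref="AT", alt="A"),
            dict(chrom="7", pos=1, ref="A", alt="N"),
        ],
    )
    def test_variant_key_invariants(self, kwargs):
        with pytest.raises(ValueError):
            VariantKey(**kwargs)

    def test_matrix_rejects_bad_codes(self):
        with pytest.raises(ValueError):
            GenotypeMatrix([VariantKey("1", 1, "A", "C")], ["S"], np.array([[7]]))

    def test_genotype_strings(self):
        assert [GT_STR[g] for g in (HOM_REF, HET, HOM_ALT, MISSING)] == [
            "0/0", "0/1", "1/1", "./.",
        ]
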