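import pytest
from hypothesis import given
from hypothesis import strategies as st

from cladefill.genome_io import (
    Annotation,
    GeneModel,
    GtfParseError,
    backtranslate_alignment,
    extract_sequences,
    parse_gtf,
    write_outputs,
)
from cladefill.intervals import GenomicInterval


def write_lines(tmp_path, lines, name="test.gtf"):
    path = tmp_path / name
    path.write_text("".join(line + "\n" for line in lines))
    return path


GTF_LINE = 'chr1\tsrc\tCDS\t11\t19\t.\t+\t0\tgene_id "g1"; transcript_id "g1.t1";'


class TestParseGtf:
    def test_coordinate_conversion(self, tmp_path):
        ann = parse_gtf(write_lines(tmp_path, [GTF_LINE]), "sp")
        gene = ann.genes["g1"]
        assert gene.cds == [GenomicInterval("chr1", 10, 19, "+")]
        assert gene.cds_length == 9

    def test_multi_exon_gene_sorted_and_summed(self, tmp_path):
        lines = [
            'chr1\tsrc\tCDS\t31\t36\t.\t+\t0\tgene_id "g1";',
            'chr1\tsrc\tCDS\t11\t19\t.\t+\t0\tgene_id "g1";',
        ]
        gene = parse_gtf(write_lines(tmp_path, lines), "sp").genes["g1"]
        assert [(iv.start, iv.end) for iv in gene.cds] == [(10, 19), (30, 36)]
        assert gene.cds_length == 15

    def test_empty_file(self, tmp_path):
        assert len(parse_gtf(write_lines(tmp_path, []), "sp")) == 0

    def test_malformed_line_names_line_number(self, tmp_path):
        path = write_lines(tmp_path, [GTF_LINE, "chr1\tonly three\tfields"])
        with pytest.raises(GtfParseError, match="line 2"):
            parse_gtf(path, "sp")

    def test_mixed_strand_gene_skipped_with_warning(self, tmp_path, caplog):
        lines = [
            'chr1\tsrc\tCDS\t11\t19\t.\t+\t0\tgene_id "g1";',
            'chr1\tsrc\tCDS\t31\t36\t.\t-\t0\tgene_id "g1";',
            GTF_LINE.replace("g1", "g2"),
        ]
        with caplog.at_level("WARNING"):
            ann = parse_gtf(write_lines(tmp_path, lines), "sp")
        assert "g1" not in ann.genes and "g2" in ann.genes
        assert any("g1" in rec.message for rec in caplog.records)

    def test_longest_cds_transcript_is_representative(self, tmp_path):
        lines = [
            'chr1\tsrc\tCDS\t1\t9\t.\t+\t0\tgene_id "g1"; transcript_id "t1";',
            'chr1\tsrc\tCDS\t1\t30\t.\t+\t0\tgene_id "g1"; transcript_id "t2";',
        ]
        gene = parse_gtf(write_lines(tmp_path, lines), "sp").genes["g1"]
        assert gene.cds_length == 30


class TestExtractSequences:
    def ann(self, intervals, strand="+"):
        a = Annotation("sp")
        a.add(GeneModel("g1", "sp", [GenomicInterval("chr1", s, e, strand) for s, e in intervals]))
        return a

    def test_plus_strand_translation_trims_stop(self):
        out = extract_sequences(self.ann([(0, 9)]), {"chr1": "ATGAAATAA"})
        gene = out.genes["g1"]
        assert gene.coding_seq == "ATGAAATAA"
        assert gene.protein == "MK"

    def test_minus_strand_reverse_complements(self):
        out = extract_sequences(self.ann([(0, 9)], "-"), {"chr1": "ATGAAATAA"})
        assert out.genes["g1"].coding_seq == "TTATTTCAT"

    def test_out_of_bounds_interval_names_gene(self):
        with pytest.raises(ValueError, match="g1"):
            extract_sequences(self.ann([(0, 12)]), {"chr1": "ATGAAATAA"})

    def test_non_multiple_of_three_trimmed_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = extract_sequences(self.ann([(0, 8)]), {"chr1": "ATGAAATAA"})
        assert out.genes["g1"].coding_seq == "ATGAAA"
        assert any("multiple of 3" in r.message for r in caplog.records)

    def test_internal_stop_translated_flagged_kept(self, caplog):
        with caplog.at_level("WARNING"):
            out = extract_sequences(self.ann([(0, 9)]), {"chr1": "ATGTAAAAA"})
        gene = out.genes["g1"]
        assert gene.protein == "M*K"
        assert gene.internal_stop

    def test_strand_symmetry(self):
        """Translating the reverse complement on the opposite strand gives
        the same protein."""
        from Bio.Seq import Seq

        seq = "ATGGCCAAATTTGGGTAA"
        fwd = extract_sequences(self.ann([(0, len(seq))]), {"chr1": seq})
        rev = extract_sequences(
            self.ann([(0, len(seq))], "-"),
            {"chr1": str(Seq(seq).reverse_complement())},
        )
        assert fwd.genes["g1"].protein == rev.genes["g1"].protein


class TestBacktranslate:
    def test_threading_with_gaps(self):
        out = backtranslate_alignment({"g": "M-K"}, {"g": "ATGAAA"})
        assert out["g"] == "ATG---AAA"

    def test_all_gap_row(self):
        assert backtranslate_alignment({"g": "---"}, {"g": ""})["g"] == "-" * 9

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError, match="g"):
            backtranslate_alignment({"g": "MK"}, {"g": "ATGAA"})

    def test_bad_character_error(self):
        with pytest.raises(ValueError, match="alphabet"):
            backtranslate_alignment({"g": "M7K"}, {"g": "ATGAAAAAA"})

    @given(
        st.lists(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_ungapping_roundtrip(self, residues, rnd):
        """Ungapping the back-translated row reproduces the coding sequence."""
        codon_of = {"A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
                    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
                    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
                    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT"}
        protein = "".join(residues)
        coding = "".join(codon_of[aa] for aa in protein)
        aligned = list(protein)
        for _ in range(rnd.randint(0, 10)):
            aligned.insert(rnd.randint(0, len(aligned)), "-")
        out = backtranslate_alignment({"g": "".join(aligned)}, {"g": coding})
        assert out["g"].replace("-", "") == coding
        assert len(out["g"]) == 3 * len(aligned)


class TestWriteOutputs:
    def test_coordinate_convention_inverse(self, tmp_path):
        gene = GeneModel(
            "g1", "sp", [GenomicInterval("chr1", 10, 19, "+")],
            coding_seq="ATGAAATAA", protein="MK",
        )
        write_outputs([gene], tmp_path / "out.gtf", tmp_path / "out.faa")
        fields = (tmp_path / "out.gtf").read_text().splitlines()[0].split("\t")
        assert (fields[3], fields[4]) == ("11", "19")

    def test_empty_gene_set_writes_valid_empty_files(self, tmp_path):
        write_outputs([], tmp_path / "o.gtf", tmp_path / "o.faa")
        assert (tmp_path / "o.gtf").read_text() == ""
        assert parse_gtf(tmp_path / "o.gtf", "sp").genes == {}

    def test_roundtrip_identity_on_fixture_annotation(self, tmp_path, small_clade):
        """parse(write(x)) reproduces every gene's interval set exactly."""
        sp = small_clade.target_species
        ann = small_clade.annotations[sp]
        write_outputs(ann, tmp_path / "rt.gtf", tmp_path / "rt.faa")
        back = parse_gtf(tmp_path / "rt.gtf", sp)
        assert set(back.genes) == set(ann.genes)
        for gid, gene in ann.genes.items():
            assert back.genes[gid].cds == gene.cds
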