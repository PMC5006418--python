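"""Format readers/writers, alphabet normalization, coordinate conventions."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncranno.cm import AnnotatedLocus
from ncranno.seqio import (Contig, FormatError, GenomicInterval, QueryRecord,
                           SeedAlignment, normalize_wuss, read_fasta,
                           read_stockholm, reverse_complement,
                           write_annotations, write_fasta, write_stockholm)


class TestFasta:
    def test_case_and_rna_normalization(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1\nacgt\n>c2\nACGU\n")
        recs = read_fasta(p)
        assert recs[0] == Contig("c1", "ACGT") and recs[0].length == 4
        assert recs[1].sequence == "ACGT"  # U -> T

    def test_invalid_character_reports_line(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1\nACXT\n")
        with pytest.raises(FormatError, match="line 2"):
            read_fasta(p)

    def test_empty_record_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1\n>c2\nACGT\n")
        with pytest.raises(FormatError, match="empty"):
            read_fasta(p)

    def test_query_header_convention(self, tmp_path):
        p = tmp_path / "q.fa"
        p.write_text(">mir-124|miRNA|CIN\nACGTACGT\n>plain\nACGT\n")
        recs = read_fasta(p)
        assert isinstance(recs[0], QueryRecord)
        assert (recs[0].family_id, recs[0].rna_class,
                recs[0].species_tag) == ("mir-124", "miRNA", "CIN")
        assert isinstance(recs[1], Contig)

    def test_round_trip(self, tmp_path, rng):
        seqs = ["".join(rng.choice(list("ACGTN"), size=137)) for _ in range(5)]
        recs = [Contig(f"c{i}", s) for i, s in enumerate(seqs)]
        p = tmp_path / "rt.fa"
        write_fasta(recs, p)
        assert read_fasta(p) == recs


class TestStockholm:
    def test_interleaved_blocks_concatenated(self, tmp_path):
        p = tmp_path / "a.sto"
        p.write_text(
            "# STOCKHOLM 1.0\n"
            "seq1 ACGUA\nseq2 ACGTA\n#=GC SS_cons <<.>>\n\n"
            "seq1 CGTAC\nseq2 CGTAC\n#=GC SS_cons .....\n//\n"
        )
        aln = read_stockholm(p)
        assert aln.columns == 10
        assert aln.rows["seq1"] == "ACGTACGTAC"  # U mapped, blocks joined
        assert aln.ss_cons == "((.))....."

    def test_missing_ss_cons_is_an_error(self, tmp_path):
        p = tmp_path / "a.sto"
        p.write_text("# STOCKHOLM 1.0\nseq1 ACGT\n//\n")
        with pytest.raises(FormatError, match="SS_cons"):
            read_stockholm(p)

    def test_unbalanced_structure_rejected(self, tmp_path):
        p = tmp_path / "a.sto"
        p.write_text("# STOCKHOLM 1.0\nseq1 ACG\n#=GC SS_cons ((.\n//\n")
        with pytest.raises(FormatError, match="unbalanced"):
            read_stockholm(p)

    def test_round_trip(self, tmp_path, toy_seed):
        p = tmp_path / "rt.sto"
        write_stockholm(toy_seed, p)
        back = read_stockholm(p, rna_class=toy_seed.rna_class)
        assert back.rows == toy_seed.rows
        assert back.ss_cons == toy_seed.ss_cons
        assert back.family_id == toy_seed.family_id

    @pytest.mark.parametrize("wuss,expected", [
        ("<<...>>", "((...))"),
        ("[{(.)}]", "(((.)))"),
        (":_-,~", "....."),
    ])
    def test_wuss_normalization(self, wuss, expected):
        assert normalize_wuss(wuss) == expected


class TestReverseComplement:
    @pytest.mark.parametrize("seq,rc", [
        ("ACGT", "ACGT"), ("AAAC", "GTTT"), ("ANT", "ANT"),
    ])
    def test_known_values(self, seq, rc):
        assert reverse_complement(seq) == rc

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGTN", max_size=200))
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestAnnotationsWriter:
    def _locus(self, contig, start, end, strand="+", fam="famA"):
        return AnnotatedLocus(fam, "snRNA",
                              GenomicInterval(contig, start, end, strand),
                              12.5, 1e-4, frozenset({"blast"}))

    def test_gff_one_based_inclusive(self, tmp_path):
        genome = [Contig("c1", "A" * 100)]
        gff = tmp_path / "a.gff3"
        write_annotations([self._locus("c1", 10, 20)], genome, gff,
                          tmp_path / "a.tsv")
        line = gff.read_text().splitlines()[1].split("\t")
        assert (line[3], line[4], line[6]) == ("11", "20", "+")
        assert line[2] == "snRNA"

    def test_empty_annotation_is_valid(self, tmp_path):
        gff = tmp_path / "e.gff3"
        write_annotations([], [], gff, tmp_path / "e.tsv")
        assert gff.read_text() == "##gff-version 3\n"

    def test_output_sorted_deterministically(self, tmp_path):
        genome = [Contig("c1", "A" * 100), Contig("c2", "A" * 100)]
        loci = [self._locus("c2", 5, 15), self._locus("c1", 50, 60),
                self._locus("c1", 5, 15)]
        gff = tmp_path / "s.gff3"
        write_annotations(loci, genome, gff, tmp_path / "s.tsv")
        rows = [l.split("\t")[:4] for l in gff.read_text().splitlines()[1:]]
        assert [(r[0], r[3]) for r in rows] == [("c1", "6"), ("c1", "51"),
                                                ("c2", "6")]

    def test_out_of_bounds_interval_rejected(self, tmp_path):
        genome = [Contig("c1", "A" * 10)]
        with pytest.raises(ValueError, match="out of bounds"):
            write_annotations([self._locus("c1", 5, 15)], genome,
                              tmp_path / "x.gff3", tmp_path / "x.tsv")

    def test_gff_round_trips_to_internal_coordinates(self, tmp_path):
        genome = [Contig("c1", "A" * 100)]
        loci = [self._locus("c1", 17, 42, "-")]
        gff = tmp_path / "rt.gff3"
        write_annotations(loci, genome, gff, tmp_path / "rt.tsv")
        f = gff.read_text().splitlines()[1].split("\t")
        start, end = int(f[3]) - 1, int(f[4])
        assert (start, end, f[6]) == (17, 42, "-")
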