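"""GFF3/FASTA/TSV readers, BED-like group output and round-trips."""

import pytest

from taxolminer import formats_io
from taxolminer.family_map import GeneGroup, detect_groups
from taxolminer.formats_io import (
    DuplicateGeneError,
    GeneLocus,
    ParseError,
    read_annotation,
    read_codon_alignment,
    read_ltr_pairs,
    write_groups,
)

TOY_GFF = """##gff-version 3
chr1\tsrc\tgene\t100\t250\t.\t+\t.\tID=geneA
chr1\tsrc\tgene\t5000\t6200\t.\t-\t.\tID=geneB
chr2\tsrc\tgene\t300\t900\t.\t+\t.\tID=geneC
"""

TOY_MAP = "geneA\tCYP725A\ngeneB\tCYP725B\ngeneC\tCYP750\n"


@pytest.fixture
def toy_gff(tmp_path):
    gff = tmp_path / "toy.gff3"
    gff.write_text(TOY_GFF)
    fam = tmp_path / "fam.tsv"
    fam.write_text(TOY_MAP)
    return gff, fam


class TestAnnotationReading:
    def test_three_gene_round_trip(self, toy_gff):
        loci = read_annotation(*toy_gff)
        assert len(loci) == 3
        by_id = {g.gene_id: g for g in loci}
        assert by_id["geneA"].family == "CYP725A"
        assert (by_id["geneA"].start, by_id["geneA"].end) == (100, 250)
        assert by_id["geneB"].strand == "-"

    def test_missing_family_becomes_unassigned(self, tmp_path, toy_gff):
        gff, _ = toy_gff
        fam = tmp_path / "partial.tsv"
        fam.write_text("geneA\tCYP725A\ngeneB\tCYP725B\n")
        loci = read_annotation(gff, fam)
        unassigned = [g for g in loci if g.family == "unassigned"]
        assert len(unassigned) == 1
        assert unassigned[0].gene_id == "geneC"

    def test_malformed_line_names_line_number(self, tmp_path):
        gff = tmp_path / "bad.gff3"
        gff.write_text("##gff-version 3\nchr1\tsrc\tgene\t100\n")
        with pytest.raises(ParseError, match="line 2"):
            read_annotation(gff)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        gff = tmp_path / "dup.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t10\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tgene\t20\t30\t.\t+\t.\tID=g1\n"
        )
        with pytest.raises(DuplicateGeneError):
            read_annotation(gff)

    def test_write_read_round_trip_preserves_coords_and_families(self, tmp_path):
        loci = [
            GeneLocus("gX", "chr3", 17, 511, "+", "CYP725A"),
            GeneLocus("gY", "chr3", 9000, 9300, "-", "BAHD"),
        ]
        gff, fam = tmp_path / "rt.gff3", tmp_path / "rt.tsv"
        formats_io.write_annotation(loci, gff, fam)
        back = read_annotation(gff, fam)
        assert [(g.gene_id, g.chrom, g.start, g.end, g.strand, g.family) for g in back] == [
            (g.gene_id, g.chrom, g.start, g.end, g.strand, g.family) for g in loci
        ]


class TestCodonAlignmentReading:
    def write_fasta(self, tmp_path, seqs):
        path = tmp_path / "pair.fasta"
        path.write_text("".join(f">{n}\n{s}\n" for n, s in seqs))
        return path

    def test_three_codon_pair(self, tmp_path):
        path = self.write_fasta(tmp_path, [("a", "TTTGGGGGG"), ("b", "TTCGGGGGG")])
        pair = read_codon_alignment(path)
        assert len(pair) == 3
        assert pair.codons_a == ("TTT", "GGG", "GGG")

    def test_non_codon_multiple_rejected(self, tmp_path):
        path = self.write_fasta(tmp_path, [("a", "A" * 10), ("b", "A" * 10)])
        with pytest.raises(ParseError, match="not codon-multiple"):
            read_codon_alignment(path)

    def test_internal_stop_rejected(self, tmp_path):
        path = self.write_fasta(tmp_path, [("a", "AAATAACCC"), ("b", "AAATAACCC")])
        with pytest.raises(ParseError, match="stop codon at position 2"):
            read_codon_alignment(path)

    def test_wrong_record_count(self, tmp_path):
        path = self.write_fasta(tmp_path, [("a", "AAACCC")])
        with pytest.raises(ParseError, match="exactly 2"):
            read_codon_alignment(path)

    def test_ambiguous_column_dropped_when_configured(self, tmp_path):
        path = self.write_fasta(tmp_path, [("a", "AAANNNCCC"), ("b", "AAAGGGCCC")])
        with pytest.raises(ParseError):
            read_codon_alignment(path)
        pair = read_codon_alignment(path, drop_ambiguous=True)
        assert len(pair) == 2


class TestGroupOutput:
    def make_group(self, label, chrom, starts, family="CYP450"):
        members = tuple(
            GeneLocus(f"{label}_m{i}", chrom, s, s + 999, "+", family)
            for i, s in enumerate(starts)
        )
        return GeneGroup(label, chrom, members)

    def test_single_group_row(self, tmp_path):
        group = self.make_group("9.1", "chr9", [1_000_000 + i * 600_000 for i in range(7)])
        out = tmp_path / "groups.tsv"
        write_groups([group], out)
        lines = out.read_text().strip().split("\n")
        assert len(lines) == 2
        fields = lines[1].split("\t")
        assert fields[0] == "chr9"
        assert int(fields[4]) == 7
        # 0-based half-open output preserves length
        locus = group.members[0]
        assert int(fields[2]) - int(fields[1]) == group.span[1] - group.span[0] + 1
        assert int(fields[1]) == group.span[0] - 1

    def test_empty_group_set_header_only(self, tmp_path):
        out = tmp_path / "empty.tsv"
        write_groups([], out)
        lines = out.read_text().strip().split("\n")
        assert lines == ["chrom\tstart\tend\tlabel\tn_members\tmember_ids"]

    def test_labels_follow_coordinate_order(self, tmp_path):
        loci = []
        for base, tag in ((1_000_000, "first"), (40_000_000, "second")):
            for i in range(7):
                s = base + i * 500_000
                loci.append(GeneLocus(f"{tag}{i}", "9", s, s + 999, "+", "CYP450"))
        groups = detect_groups(loci, family_filter={"CYP450"}, max_gap=5_260_000)
        out = tmp_path / "labeled.tsv"
        write_groups(groups, out)
        lines = out.read_text().strip().split("\n")[1:]
        assert [l.split("\t")[3] for l in lines] == ["9.1", "9.2"]


class TestLTRPairs:
    def test_pairing_by_suffix(self, tmp_path):
        seq = "ACGT" * 50
        path = tmp_path / "ltrs.fasta"
        path.write_text(f">e1_5LTR\n{seq}\n>e1_3LTR\n{seq}\n")
        elements = read_ltr_pairs(path)
        assert len(elements) == 1
        assert elements[0].element_id == "e1"

    def test_unmatched_pair_rejected(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(f">e1_5LTR\n{'ACGT' * 50}\n")
        with pytest.raises(ParseError, match="unmatched"):
            read_ltr_pairs(path)


class TestHitsTable:
    def test_reads_five_columns(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("A\tB\t100.5\t1e-30\t200\nB\tA\t100.5\t1e-30\t200\n")
        hits = formats_io.read_hits(path)
        assert list(hits.columns) == formats_io.HITS_COLUMNS
        assert len(hits) == 2

    def test_negative_bitscore_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("A\tB\t-5\t1e-30\t200\n")
        with pytest.raises(ParseError):
            formats_io.read_hits(path)
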