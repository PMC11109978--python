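"""Genome parsing, IGR extraction and Stockholm round-tripping."""

import pytest

from igrscout import genome_io as gio
from igrscout.genome_io import (ConsistencyError, extract_igrs, pct_gc,
                                read_annotated_genome, read_stockholm,
                                ss_pairs, write_gff3_fasta, write_stockholm)

from conftest import cds, make_alignment, make_genome, rna

GBK = """\
LOCUS       TESTREC                  300 bp    DNA     linear   BCT 01-JAN-2020
DEFINITION  synthetic test record.
ACCESSION   TESTREC
VERSION     TESTREC.1
FEATURES             Location/Qualifiers
     source          1..300
     CDS             1..90
                     /locus_tag="gene1"
                     /product="hypothetical protein"
     CDS             complement(121..210)
                     /locus_tag="gene2"
                     /product="membrane protein"
     tRNA            241..300
                     /locus_tag="trna1"
                     /product="tRNA-Ala"
ORIGIN
        1 {seq}
//
"""


def _gbk_text():
    seq = "acgt" * 75
    lines = []
    for i in range(0, 300, 60):
        chunk = seq[i:i + 60]
        grouped = " ".join(chunk[j:j + 10] for j in range(0, 60, 10))
        lines.append(f"{i + 1:>9} {grouped}")
    return GBK.replace("        1 {seq}", "\n".join(lines))


def test_read_genbank_features(tmp_path):
    p = tmp_path / "rec.gbk"
    p.write_text(_gbk_text())
    g = read_annotated_genome(p, format="genbank")
    assert len(g.features) == 3
    kinds = [f.kind for f in g.features]
    assert kinds == ["CDS", "CDS", "known_rna"]
    assert g.features[0].start == 0 and g.features[0].end == 90
    assert g.features[1].strand == "-"
    assert g.sequence == ("ACGT" * 75)


def test_gff3_coordinate_conversion(tmp_path):
    (tmp_path / "a.gff3").write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tCDS\t101\t200\t.\t+\t0\tID=g1;product=hypothetical protein\n")
    (tmp_path / "a.fna").write_text(">chr1\n" + "ACGT" * 100 + "\n")
    g = read_annotated_genome(tmp_path / "a.gff3", format="gff3+fasta")
    assert (g.features[0].start, g.features[0].end) == (100, 200)


def test_gff3_fasta_id_mismatch(tmp_path):
    (tmp_path / "a.gff3").write_text(
        "##gff-version 3\nchrX\tsrc\tCDS\t1\t30\t.\t+\t0\tID=g1\n")
    (tmp_path / "a.fna").write_text(">chr1\n" + "ACGT" * 10 + "\n")
    with pytest.raises(ConsistencyError):
        read_annotated_genome(tmp_path / "a.gff3", format="gff3+fasta")


def test_gff3_round_trip_coordinates(tmp_path):
    g = make_genome([cds(10, 100, "+"), cds(150, 300, "-"), rna(320, 380)],
                    length=400)
    write_gff3_fasta(g, tmp_path / "g.gff3", tmp_path / "g.fna")
    g2 = read_annotated_genome(tmp_path / "g.gff3", format="gff3+fasta")
    assert [(f.start, f.end, f.strand, f.kind) for f in g2.features] == \
        [(f.start, f.end, f.strand, f.kind) for f in g.features]
    assert g2.sequence == g.sequence


def test_unknown_strand_rejected(tmp_path):
    (tmp_path / "a.gff3").write_text(
        "##gff-version 3\nchr1\tsrc\tCDS\t1\t30\t.\t.\t0\tID=g1\n")
    (tmp_path / "a.fna").write_text(">chr1\n" + "ACGT" * 10 + "\n")
    with pytest.raises(gio.ParseError):
        read_annotated_genome(tmp_path / "a.gff3", format="gff3+fasta")


class TestExtractIgrs:
    def test_simple_gap(self):
        g = make_genome([cds(0, 100), cds(160, 300)], length=300)
        igrs = extract_igrs(g, min_len=50)
        assert len(igrs) == 1
        igr = igrs[0]
        assert (igr.start, igr.end, igr.length_nt) == (100, 160, 60)
        assert igr.left_gene.feature_id == "cds_0"
        assert igr.right_gene.feature_id == "cds_160"

    def test_below_threshold(self):
        g = make_genome([cds(0, 100), cds(130, 300)], length=300)
        assert extract_igrs(g, min_len=50) == []

    def test_circular_wraparound(self):
        g = make_genome([cds(50, 100), cds(200, 250)], length=300, circular=True)
        igrs = extract_igrs(g, min_len=25)
        spans = sorted((i.start, i.end) for i in igrs)
        assert spans == [(100, 200), (250, 350)]
        wrap = [i for i in igrs if i.end > 300][0]
        assert wrap.length_nt == 100
        assert wrap.sequence == g.sequence[250:] + g.sequence[:50]

    def test_known_rna_overlap_marks_status(self):
        g = make_genome([cds(0, 100), rna(120, 160), cds(200, 300)], length=300)
        igrs = extract_igrs(g, min_len=25)
        assert len(igrs) == 1
        assert igrs[0].status == "known_rna"

    def test_partition_never_overlaps_cds(self):
        import random
        rng = random.Random(0)
        for _ in range(20):
            feats, pos = [], 0
            while pos < 900:
                pos += rng.randint(5, 60)
                end = pos + rng.randint(30, 120)
                if end >= 1000:
                    break
                feats.append(cds(pos, end))
                pos = end
            g = make_genome(feats, length=1000)
            covered = set()
            for f in feats:
                covered.update(range(f.start, f.end))
            for igr in extract_igrs(g, min_len=1):
                assert covered.isdisjoint(range(igr.start, min(igr.end, 1000)))


class TestPctGc:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGC", 50.0), ("GGGG", 100.0), ("ANGC", 200 / 3), ("atgc", 50.0),
    ])
    def test_values(self, seq, expected):
        assert pct_gc(seq) == pytest.approx(expected)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            pct_gc("")

    def test_all_ambiguous_is_nan(self):
        import math
        assert math.isnan(pct_gc("NNNN"))


class TestStockholm:
    def test_round_trip(self, tmp_path):
        aln = make_alignment(["ACGU-ACG", "ACGUUACG", "AC-UUACG"],
                             ss="<<....>>")
        aln.extra_gc["cons"] = "ACGUUACG"
        aln.gf["AU"] = "igrscout test"
        p = tmp_path / "m.sto"
        write_stockholm(aln, p)
        back = read_stockholm(p)
        assert back.motif_id == aln.motif_id
        assert [r.seq for r in back.rows] == [r.seq for r in aln.rows]
        assert [(r.igr_id, r.start, r.end, r.strand) for r in back.rows] == \
            [(r.igr_id, r.start, r.end, r.strand) for r in aln.rows]
        assert back.ss_cons == aln.ss_cons
        assert back.extra_gc == aln.extra_gc

    def test_rewrite_is_byte_stable(self, tmp_path):
        aln = make_alignment(["ACGUACG-", "ACGUACGG"], ss="<<....>>")
        write_stockholm(aln, tmp_path / "a.sto")
        write_stockholm(read_stockholm(tmp_path / "a.sto"), tmp_path / "b.sto")
        assert (tmp_path / "a.sto").read_bytes() == (tmp_path / "b.sto").read_bytes()

    def test_unbalanced_structure_rejected(self, tmp_path):
        aln = make_alignment(["ACGUAC", "ACGUAC"], ss="<<.>>>")
        with pytest.raises(ValueError):
            write_stockholm(aln, tmp_path / "m.sto")

    def test_empty_alignment_rejected(self, tmp_path):
        aln = make_alignment([])
        with pytest.raises(ValueError):
            write_stockholm(aln, tmp_path / "m.sto")

    def test_ragged_alignment_rejected(self, tmp_path):
        p = tmp_path / "m.sto"
        p.write_text("# STOCKHOLM 1.0\nigr0/0-4 ACGU\nigr1/0-6 ACGUAC\n//\n")
        with pytest.raises(gio.ParseError):
            read_stockholm(p)


def test_ss_pairs_nesting_and_errors():
    assert ss_pairs("<<..>>") == [(0, 5), (1, 4)]
    assert ss_pairs("..((..))<.>") == [(2, 7), (3, 6), (8, 10)]
    with pytest.raises(ValueError):
        ss_pairs("<<.>")
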