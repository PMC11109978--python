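"""Conservation, covariation, consensus folding and feature detectors."""

import random

import pytest

from igrscout import structure_analysis as sa
from igrscout.genome_io import GeneFeature, IGR, ss_pairs

from conftest import make_alignment


class TestConservationProfile:
    def test_levels(self):
        aln = make_alignment(["GGG"] * 9 + ["GAC"])
        prof = sa.conservation_profile(aln)
        assert (prof[0].level, prof[0].dominant_nt) == ("n97", "G")
        assert prof[1].level == "n90"
        # 3G + 3A + 4C: dominant 40% -> variable
        aln2 = make_alignment(["G"] * 3 + ["A"] * 3 + ["C"] * 4)
        assert sa.conservation_profile(aln2)[0].level == "variable"
        assert sa.conservation_profile(aln2)[0].dominant_nt is None

    def test_gappy_column_is_variable(self):
        aln = make_alignment(["G-", "G-", "GG", "G-"])
        prof = sa.conservation_profile(aln)
        assert prof[1].level == "variable"
        assert prof[1].gap_fraction == 0.75

    def test_zero_width_is_error(self):
        with pytest.raises(ValueError):
            sa.conservation_profile(make_alignment([]))


class TestPairCovariation:
    def test_two_pair_types_covarying(self):
        aln = make_alignment(["GC", "GC", "AU"])
        ev = sa.pair_covariation(aln, 0, 1)
        assert (ev.n_pair_types, ev.klass) == (2, "covarying")
        assert ev.n_canonical == 3 and ev.n_noncanonical == 0

    def test_single_pair_type_compatible(self):
        assert sa.pair_covariation(make_alignment(["GC"] * 3), 0, 1).klass == \
            "compatible"

    def test_noncanonical_unsupported(self):
        assert sa.pair_covariation(make_alignment(["GA"] * 3), 0, 1).klass == \
            "unsupported"

    def test_fewer_than_three_rows_unsupported(self):
        assert sa.pair_covariation(make_alignment(["GC", "AU"]), 0, 1).klass == \
            "unsupported"

    def test_matrix_matches_pointwise(self):
        rng = random.Random(0)
        aln = make_alignment(["".join(rng.choice("ACGU-") for _ in range(12))
                              for _ in range(8)])
        klass = sa.pair_class_matrix(aln)
        names = {0: "unsupported", 1: "compatible", 2: "covarying"}
        for i in range(12):
            for j in range(i + 1, 12):
                assert names[int(klass[i, j])] == sa.pair_covariation(aln, i, j).klass

    def test_adding_canonical_row_never_demotes_to_unsupported(self):
        rows = ["GC", "GC", "AU"]
        assert sa.pair_covariation(make_alignment(rows), 0, 1).klass == "covarying"
        for extra in ("GC", "AU", "UA", "GU"):
            klass = sa.pair_covariation(make_alignment(rows + [extra]), 0, 1).klass
            assert klass in ("covarying", "compatible")


def _stem_alignment(n_rows=6, flank=5):
    """Rows share one 5-bp covarying stem separated by a variable loop."""
    rng = random.Random(4)
    pairs5 = ["GC", "CG", "AU", "UA"]
    rows = []
    stems = []
    for r in range(n_rows):
        stem = [pairs5[(r + k) % 4] for k in range(5)]
        stems.append(stem)
    for r in range(n_rows):
        left = "".join(s[0] for s in stems[r])
        right = "".join(s[1] for s in stems[r][::-1])
        loop = "".join(rng.choice("ACGU") for _ in range(flank))
        rows.append(left + loop + right)
    return make_alignment(rows)


class TestFoldConsensus:
    def test_recovers_planted_stem(self):
        aln = _stem_alignment()
        ss = sa.fold_consensus(aln)
        assert ss == "<<<<<.....>>>>>"

    def test_no_pairs_all_dots(self):
        aln = make_alignment(["AAAAAAAA"] * 4)
        assert sa.fold_consensus(aln) == "........"

    def test_always_balanced_and_min_loop(self):
        rng = random.Random(8)
        for _ in range(40):
            w = rng.randint(6, 20)
            aln = make_alignment(["".join(rng.choice("ACGU") for _ in range(w))
                                  for _ in range(rng.randint(3, 6))])
            ss = sa.fold_consensus(aln)
            pairs = ss_pairs(ss)  # raises if unbalanced
            assert all(j - i > 3 for i, j in pairs)
            assert len(ss) == w


class TestHelixParsing:
    def test_count_stems_example(self):
        assert sa.count_stems("<<<...>>>..<<<<...>>>>") == 2

    def test_short_helices_not_counted(self):
        assert sa.count_stems("<<....>>") == 0

    def test_bulged_helix_is_one_stem(self):
        assert sa.count_stems("<<<.<<....>>.>>>") == 1
        assert sa.count_stems("<<<<<...<<....>>..>>>>>") == 1

    def test_hairpins_ordering(self):
        hps = sa.hairpins_of("<<<...>>>....<<<<....>>>>")
        assert [h["stem_bp"] for h in hps] == [3, 4]
        assert hps[-1]["stem3"] == 24


class TestFindTerminator:
    def _hairpin(self, tail):
        #            0123456789...
        seq = "AAGCGCGCGC" + "UUUA" + "GCGCGCGCUU" + tail
        fold = ".." + "<" * 8 + "...." + ">" * 8 + ".." + "." * len(tail)
        return seq, fold

    def test_six_u_tail_positive(self):
        seq = "GCGCGCGC" + "GUUA" + "GCGCGCGC" + "UUUUUUAA"
        fold = "<" * 8 + "...." + ">" * 8 + "." * 8
        call = sa.find_terminator(seq, fold=fold, min_stem=6)
        assert call.is_terminator and call.u_run == 6
        assert call.stem_bp == 8

    def test_four_u_tail_negative(self):
        seq = "GCGCGCGC" + "GUUA" + "GCGCGCGC" + "UUUUAAAA"
        fold = "<" * 8 + "...." + ">" * 8 + "." * 8
        call = sa.find_terminator(seq, fold=fold, min_stem=6)
        assert not call.is_terminator and call.u_run == 4

    def test_no_hairpin_empty_call(self):
        call = sa.find_terminator("ACGU" * 5, fold="." * 20)
        assert not call.is_terminator and call.stem_bp == 0

    def test_scan_mode_finds_three_prime_hairpin(self):
        seq = "CCCCC" + "GGCGGCGG" + "UUCA" + "CCGCCGCC" + "UUUUUUCC"
        call = sa.find_terminator(seq, min_stem=6)
        assert call.is_terminator and call.u_run == 6


class TestFindSd:
    def _setup(self, upstream):
        seq = "C" * 40 + upstream + "ATG" + "C" * 17
        gene = GeneFeature("g", 40 + len(upstream), 60 + len(upstream), "+", "CDS")
        igr = IGR(igr_id="i", genome_id="g", start=0, end=40 + len(upstream),
                  sequence=seq[:40 + len(upstream)])
        return igr, gene, seq

    def test_full_core(self):
        igr, gene, seq = self._setup("AGGAGGTAACAT")
        call = sa.find_sd(igr, gene, genome_seq=seq)
        assert (call.core_len, call.spacing_to_start) == (6, 6)

    def test_partial_core_with_n(self):
        igr, gene, seq = self._setup("GGAGNTAACAT")
        call = sa.find_sd(igr, gene, genome_seq=seq)
        assert (call.core_len, call.spacing_to_start) == (4, 7)

    def test_no_match(self):
        igr, gene, seq = self._setup("CCCCCCCCCCCC")
        assert sa.find_sd(igr, gene, genome_seq=seq) is None

    def test_minus_strand_gene(self):
        # upstream of a '-' gene lies to its right in forward coordinates
        core_rc = "CCTCCT"  # revcomp of AGGAGG
        seq = "G" * 20 + "CAT" + "ATTGTA" + core_rc + "G" * 40
        gene = GeneFeature("g", 0, 23, "-", "CDS")
        igr = IGR(igr_id="i", genome_id="g", start=23, end=len(seq),
                  sequence=seq[23:])
        call = sa.find_sd(igr, gene, genome_seq=seq)
        assert call is not None and call.core_len == 6


class TestFindUorf:
    def test_conserved_uorf(self):
        aln = make_alignment(["AUGAAAUAAGG"] * 5)
        call = sa.find_uorf(aln)
        assert call is not None and call.conserved
        assert (call.start_column, call.stop_column) == (0, 6)

    def test_no_in_frame_stop(self):
        assert sa.find_uorf(make_alignment(["AUGAAAAAAGG"] * 5)) is None

    def test_start_below_threshold(self):
        rows = ["AUGAAAUAA"] * 2 + ["CCCAAAUAA"] * 2
        assert sa.find_uorf(make_alignment(rows), min_rows_fraction=0.8) is None

    def test_too_few_rows(self):
        assert sa.find_uorf(make_alignment(["AUGAAAUAA"] * 2)) is None

    def test_gapped_rows_share_columns(self):
        rows = ["AUG-AAAUAA", "AUGCAAAUAA", "AUG-AAAUAA", "AUGCAAAUAA"]
        call = sa.find_uorf(make_alignment(rows))
        assert call is None or call.start_column == 0
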