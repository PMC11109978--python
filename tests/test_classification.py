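"""Category rule engine, evidence extraction and the census."""

import random

import pytest

from igrscout import classification as cls
from igrscout.structure_analysis import UorfCall

from conftest import make_alignment


def ev(**kw):
    ctx_kw = {k: kw.pop(k) for k in list(kw)
              if k in ("downstream_same_strand_fraction", "dominant_context_key",
                       "dominant_gene_fraction", "copies_per_genome_median",
                       "orientation_consistent")}
    return cls.MotifEvidence(context=cls.GeneContext(**ctx_kw), **kw)


UORF = UorfCall(start_column=0, stop_column=30, frame_consistent_fraction=1.0,
                conserved=True)


class TestClassifyRules:
    # rank fixtures: structured but without gene-context evidence, so no
    # named rule (including sRNA, which needs near-zero structure) fires
    def test_few_uniques_rank_lrc(self):
        assert cls.classify(ev(n_unique=4, n_stems=2,
                               downstream_same_strand_fraction=0.6)) == "LRC"

    def test_mid_uniques_rank_mrc(self):
        assert cls.classify(ev(n_unique=12, n_stems=2,
                               downstream_same_strand_fraction=0.6)) == "MRC"

    def test_many_uniques_good_model_hrc(self):
        assert cls.classify(ev(n_unique=25, n_stems=3, n_covarying_pairs=5,
                               n_conserved_cols_90=15,
                               downstream_same_strand_fraction=0.6)) == "HRC"

    def test_many_uniques_poor_model_unnamed(self):
        assert cls.classify(ev(n_unique=25, n_covarying_pairs=0,
                               n_conserved_cols_90=2,
                               downstream_same_strand_fraction=0.6)) == "Unnamed"

    def test_strong_riboswitch(self):
        e = ev(n_unique=30, n_stems=4, n_covarying_pairs=6, has_terminator=True,
               downstream_same_strand_fraction=1.0,
               dominant_context_key="transporter", dominant_gene_fraction=1.0)
        assert cls.classify(e) == "SRC"

    def test_weak_riboswitch_when_less_evidence(self):
        e = ev(n_unique=30, n_stems=2, n_covarying_pairs=2,
               downstream_same_strand_fraction=1.0,
               dominant_context_key="metabolic", dominant_gene_fraction=1.0)
        assert cls.classify(e) == "WRC"

    def test_mrsc_outranks_utr_rules(self):
        e = ev(n_unique=30, n_stems=4, n_covarying_pairs=6, has_terminator=True,
               downstream_same_strand_fraction=1.0,
               dominant_context_key="transposase_like", dominant_gene_fraction=1.0,
               copies_per_genome_median=8)
        assert cls.classify(e) == "MRSC"

    def test_mrsc_by_orientation_and_transposase(self):
        e = ev(copies_per_genome_median=1, orientation_consistent=False,
               dominant_context_key="transposase_like")
        assert cls.classify(e) == "MRSC"

    def test_uorf_outranks_riboswitch(self):
        e = ev(n_unique=30, n_stems=4, n_covarying_pairs=6, has_terminator=True,
               downstream_same_strand_fraction=1.0,
               dominant_context_key="metabolic", dominant_gene_fraction=1.0,
               uorf=UORF)
        assert cls.classify(e) == "uORFC"

    def test_sorf_when_not_utr_positioned(self):
        e = ev(uorf=UORF, sorf_like=True,
               downstream_same_strand_fraction=0.2)
        assert cls.classify(e) == "sORF"

    def test_terminator_stem(self):
        e = ev(n_unique=30, n_stems=1, n_covarying_pairs=4, has_terminator=True,
               downstream_same_strand_fraction=0.3)
        assert cls.classify(e) == "TSC"

    def test_short_u_tail_is_not_tsc(self):
        # a hairpin followed by only four U never sets has_terminator
        e = ev(n_unique=30, n_stems=1, n_covarying_pairs=4, has_terminator=False,
               downstream_same_strand_fraction=0.3)
        assert cls.classify(e) != "TSC"
        assert cls.classify(e) == "sRNA"

    def test_ribosomal_leader_before_hrc(self):
        e = ev(n_unique=40, n_covarying_pairs=6, n_conserved_cols_90=20,
               n_stems=2, downstream_same_strand_fraction=1.0,
               dominant_context_key="ribosomal_protein", dominant_gene_fraction=1.0)
        assert cls.classify(e) == "RLC"

    def test_protein_binding_candidate(self):
        e = ev(n_unique=30, n_stems=2, n_covarying_pairs=3,
               downstream_same_strand_fraction=1.0,
               dominant_context_key="nucleic_acid_binding",
               dominant_gene_fraction=1.0)
        assert cls.classify(e) == "PBC"

    def test_rna_thermometer(self):
        e = ev(downstream_same_strand_fraction=0.9,
               dominant_context_key="temperature")
        assert cls.classify(e) == "RTC"

    def test_srna(self):
        e = ev(n_unique=30, n_stems=0,
               downstream_same_strand_fraction=0.2)
        assert cls.classify(e) == "sRNA"


class TestClassifyTotality:
    def test_fuzz_total_function_covers_all_ranks(self):
        rng = random.Random(0)
        keys = ["unknown", "other", "metabolic", "transporter",
                "ribosomal_protein", "nucleic_acid_binding", "temperature",
                "transposase_like"]
        seen = set()
        for _ in range(10000):
            e = ev(
                n_unique=rng.randrange(0, 50),
                n_stems=rng.randrange(0, 6),
                n_covarying_pairs=rng.randrange(0, 10),
                n_conserved_cols_90=rng.randrange(0, 30),
                has_terminator=rng.random() < 0.3,
                sd_overlaps_structure=rng.random() < 0.3,
                uorf=UORF if rng.random() < 0.2 else None,
                sorf_like=rng.random() < 0.1,
                downstream_same_strand_fraction=rng.random(),
                dominant_context_key=rng.choice(keys),
                dominant_gene_fraction=rng.random(),
                copies_per_genome_median=rng.choice([0, 1, 1, 2, 5]),
                orientation_consistent=rng.random() < 0.8,
            )
            label = cls.classify(e)
            assert label in cls.CATEGORIES
            seen.add(label)
        assert {"LRC", "MRC", "HRC", "Unnamed"} <= seen

    def test_label_independent_of_motif_order(self):
        rng = random.Random(1)
        evs = []
        for _ in range(50):
            evs.append(ev(n_unique=rng.randrange(0, 40),
                          n_stems=rng.randrange(0, 5),
                          n_covarying_pairs=rng.randrange(0, 8),
                          downstream_same_strand_fraction=rng.random(),
                          dominant_context_key=rng.choice(["metabolic", "other"]),
                          dominant_gene_fraction=rng.random()))
        labels = [cls.classify(e) for e in evs]
        shuffled = list(enumerate(evs))
        rng.shuffle(shuffled)
        for idx, e in shuffled:
            assert cls.classify(e) == labels[idx]


class TestLexicon:
    @pytest.mark.parametrize("product,key", [
        ("ABC transporter permease", "transporter"),
        ("30S ribosomal protein S4", "ribosomal_protein"),
        ("acetolactate synthase large subunit", "metabolic"),
        ("IS5 family transposase", "transposase_like"),
        ("transcriptional regulator, MarR family", "nucleic_acid_binding"),
        ("heat-shock chaperone", "temperature"),
        ("hypothetical protein", "other"),
        ("", "unknown"),
    ])
    def test_classify_product(self, product, key):
        assert cls.classify_product(product) == key

    def test_yaml_lexicon_loads(self, tmp_path):
        p = tmp_path / "lex.yaml"
        p.write_text(cls.DEFAULT_LEXICON_YAML)
        lex = cls.load_lexicon(p)
        assert cls.classify_product("sodium:proline symporter", lex) == "transporter"


class TestSummarize:
    def test_counts_and_total(self):
        labels = [("m1", "SRC"), ("m2", "SRC"), ("m3", "LRC"),
                  ("m4", "LRC"), ("m5", "LRC")]
        statuses = ["known_orf"] * 10 + ["unknown"] * 3
        census = cls.summarize(labels, statuses)
        d = dict(zip(census["Motif category"], census["Total counts"]))
        assert d["Strong riboswitch candidates"] == 2
        assert d["Low-ranking candidates"] == 3
        assert d["Known ORFs"] == 10
        assert d["Total"] == 15

    def test_empty_all_zero(self):
        census = cls.summarize([], [])
        assert set(census["Total counts"]) == {0}

    def test_row_order_stable(self):
        census = cls.summarize([], [])
        assert list(census["Motif category"])[:4] == [
            "Known ORFs", "Low-ranking candidates", "Unnamed",
            "Mobile/repeat sequence candidates"]
        assert list(census["Motif category"])[-1] == "Total"


class TestExtractEvidence:
    def test_on_constructed_motif(self):
        from conftest import cds, make_genome
        genome = make_genome(
            [cds(0, 60, "+", product="hypothetical protein"),
             cds(200, 290, "+", product="ABC transporter permease")],
            length=300)
        aln = make_alignment(["ACGUACGUACGUACGUACGU"] * 4)
        for row in aln.rows:
            row.genome_id = genome.genome_id
            row.start, row.end = 170, 190
        aln.ss_cons = "." * 20
        evd = cls.extract_evidence(aln, [genome])
        assert evd.context.downstream_same_strand_fraction == 1.0
        assert evd.context.dominant_context_key == "transporter"
        assert evd.n_stems == 0 and not evd.has_terminator

    def test_unknown_genome_is_error(self):
        aln = make_alignment(["ACGU"] * 3)
        with pytest.raises(KeyError):
            cls.extract_evidence(aln, [])
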