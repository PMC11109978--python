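"""End-to-end orchestration: ingest -> select -> filter -> cluster -> analyze
-> classify -> census.

``run_pipeline`` takes a list of annotated genomes (real or synthetic) and
returns every intermediate product; with an output directory it also writes
the deterministic artifact set (scatter TSV, census TSV, per-motif Stockholm
and JSON reports), so two runs with the same inputs are byte-identical.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from . import classification as cls
from . import coding_filter as cf
from . import gc_igr_select as sel
from . import motif_grouping as mg
from . import structure_analysis as sa
from .genome_io import Genome, extract_igrs

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("igrscout")


@dataclass
class PipelineConfig:
    """Tunable knobs of the full pipeline (defaults are the shipped ones)."""

    min_igr_len: int = 25
    selection_coverage: float = 0.90
    fallback_gc_min: float = 50.0
    fallback_len_min: int = 120
    min_codons: int = 50
    kmer_k: int = 6
    cluster_threshold: float = 0.35
    min_loop: int = 3
    bonus_covary: float = 3.0
    bonus_compatible: float = 1.0
    rules: cls.RuleConfig = field(default_factory=cls.RuleConfig)


@dataclass
class PipelineResult:
    igrs: list
    region: sel.SelectionRegion | None
    candidates: list
    motifs: list
    evidence: dict
    labels: list
    census: object  # pandas DataFrame


def run_pipeline(genomes: list[Genome], config: PipelineConfig | None = None,
                 outdir: str | None = None) -> PipelineResult:
    cfg = config or PipelineConfig()

    igrs = []
    for g in genomes:
        igrs.extend(extract_igrs(g, min_len=cfg.min_igr_len))
    log.info("extracted %d IGRs from %d genomes", len(igrs), len(genomes))

    known = [(i.pct_gc, i.length_nt) for i in igrs if i.status == "known_rna"]
    unknown = [(i.pct_gc, i.length_nt) for i in igrs if i.status == "unknown"]
    if known:
        region = sel.fit_selection_region(known, unknown,
                                          coverage=cfg.selection_coverage)
    else:
        region = sel.SelectionRegion(cfg.fallback_gc_min, cfg.fallback_len_min,
                                     0, 0, 0.0)
        log.info("no annotated RNAs; falling back to absolute thresholds")
    candidates = sel.select_candidates(igrs, region)
    log.info("selection region gc_min=%.1f len_min=%d: %d candidates "
             "(%d known inside, %d unknown inside)", region.gc_min,
             region.len_min, len(candidates), region.n_known_inside,
             region.n_unknown_inside)

    kept = []
    n_coding = 0
    for igr in candidates:
        if cf.flag_coding(igr, min_codons=cfg.min_codons):
            n_coding += 1
        else:
            kept.append(igr)
    log.info("coding filter removed %d of %d candidates", n_coding, len(candidates))

    groups = mg.cluster_homologs(kept, k=cfg.kmer_k,
                                 threshold=cfg.cluster_threshold)
    log.info("clustered %d candidates into %d motif groups "
             "(%d with >= 2 members)", len(kept), len(groups),
             sum(1 for g in groups if len(g) > 1))

    motifs = []
    for n, group in enumerate(groups):
        motif = mg.build_motif(f"motif{n:04d}", group, k=cfg.kmer_k,
                               max_utr_gap=cfg.rules.max_utr_gap)
        _fold_oriented(motif, group, cfg)
        motifs.append(motif)

    lexicon = cls.load_lexicon()
    evidence = {}
    labels = []
    for motif in motifs:
        ev = cls.extract_evidence(motif, genomes, lexicon=lexicon, cfg=cfg.rules)
        evidence[motif.motif_id] = ev
        labels.append((motif.motif_id, cls.classify(ev, cfg.rules)))
    census = cls.summarize(labels, [i.status for i in igrs])
    log.info("classified %d motifs", len(labels))

    result = PipelineResult(igrs=igrs, region=region, candidates=candidates,
                            motifs=motifs, evidence=evidence, labels=labels,
                            census=census)
    if outdir is not None:
        _write_outputs(result, genomes, outdir)
    return result


def _fold_oriented(motif, group, cfg: PipelineConfig) -> None:
    """Fold the motif, picking the orientation with the most covariation.

    Covariation is orientation-sensitive: a compensatory G·U swap reads as
    the non-pairing C·A in the antisense direction, so the sense strand of a
    structured RNA is the reading whose consensus fold carries more
    covarying pairs (then the higher fold score).  On an exact tie the
    orientation putting more members immediately upstream of a same-strand
    gene (the 5'-UTR convention) wins, then the seed orientation.
    """
    def _fold_and_score(m):
        ss = sa.fold_consensus(m, min_loop=cfg.min_loop,
                               bonus_covary=cfg.bonus_covary,
                               bonus_compatible=cfg.bonus_compatible)
        if "<" not in ss:
            return ss, 0, 0.0
        klass = sa.pair_class_matrix(m)
        from .genome_io import ss_pairs
        pairs = ss_pairs(ss)
        ncov = sum(1 for i, j in pairs if klass[i, j] == 2)
        score = sum(cfg.bonus_covary if klass[i, j] == 2 else cfg.bonus_compatible
                    for i, j in pairs)
        return ss, ncov, score

    motif.column_stats = sa.conservation_profile(motif)
    ss1, ncov1, score1 = _fold_and_score(motif)
    motif.ss_cons = ss1
    if len(motif.rows) < sa.MIN_PAIR_ROWS:
        return
    strands = [r.strand for r in motif.rows]
    ds1 = mg._downstream_count(group, strands, cfg.rules.max_utr_gap)
    mg.flip_motif(motif)
    motif.column_stats = sa.conservation_profile(motif)
    ss2, ncov2, score2 = _fold_and_score(motif)
    ds2 = mg._downstream_count(group, [r.strand for r in motif.rows],
                               cfg.rules.max_utr_gap)
    if (ncov2, score2, ds2) > (ncov1, score1, ds1):
        motif.ss_cons = ss2
    else:
        mg.flip_motif(motif)
        motif.column_stats = sa.conservation_profile(motif)
        motif.ss_cons = ss1


def _write_outputs(res: PipelineResult, genomes, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    sel.export_scatter(res.igrs, res.region, os.path.join(outdir, "igr_scatter.tsv"))
    res.census.to_csv(os.path.join(outdir, "census.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "motifs.tsv"), "w") as fh:
        fh.write("motif_id\tcategory\tn_total\tn_unique\tmembers\n")
        for (mid, label), motif in zip(res.labels, res.motifs):
            fh.write(f"{mid}\t{label}\t{motif.n_total}\t{motif.n_unique}\t"
                     + ",".join(r.igr_id for r in motif.rows) + "\n")
    motif_dir = os.path.join(outdir, "motifs")
    by_label = dict(res.labels)
    for motif in res.motifs:
        cls.report_motif(motif, res.evidence[motif.motif_id],
                         by_label[motif.motif_id], genomes, motif_dir)
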