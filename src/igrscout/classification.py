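"""Motif categorization: gene-context evidence extraction and the rule engine.

Each motif is summarized as a MotifEvidence record (representation,
structure, covariation, terminator/SD/uORF features, gene context) and passed
through a fixed-precedence rule list that assigns exactly one category:

* named candidates — MRSC (mobile/repeat), uORFC, sORF, TSC (terminator
  stem), RLC (ribosomal leader), PBC (protein binding), RTC (RNA
  thermometer), SRC / WRC (strong / weak riboswitch candidates), sRNA —
* or a rank — LRC / MRC / HRC / Unnamed — when no named rule fires.

Selfish elements outrank cis-regulatory calls and the uORF rule outranks the
riboswitch rules, so a motif with a conserved upstream ORF is reported as a
uORF candidate even when it also looks riboswitch-like.
"""

from __future__ import annotations

import json
import os
import re
from dataclasses import dataclass, field

import yaml

from .genome_io import Genome, IGR, MotifAlignment, ss_pairs, write_stockholm
from . import structure_analysis as sa

__all__ = [
    "GeneContext", "MotifEvidence", "RuleConfig", "CATEGORIES",
    "DEFAULT_LEXICON_YAML", "load_lexicon", "classify_product",
    "extract_evidence", "classify", "summarize", "report_motif",
]

CATEGORIES = ["Unnamed", "LRC", "MRC", "HRC", "SRC", "WRC", "uORFC", "sORF",
              "PBC", "RLC", "RTC", "MRSC", "sRNA", "TSC"]

# editable default keyword lexicon: class -> regex alternatives
DEFAULT_LEXICON_YAML = """\
ribosomal_protein:
  - 'ribosomal protein|30S|50S'
nucleic_acid_binding:
  - 'transcription(al)? regulator|DNA[- ]binding|helix-turn-helix'
transposase_like:
  - 'transposase|integrase|nuclease|helicase'
temperature:
  - 'heat[- ]shock|cold[- ]shock|chaperone'
transporter:
  - 'transporter|permease|ABC|symporter|antiporter'
metabolic:
  - 'synthase|synthetase|dehydrogenase|reductase|transferase|ligase|isomerase|kinase'
"""

# match order: specific classes before the broad metabolic catch-all
_LEXICON_ORDER = ["ribosomal_protein", "transposase_like", "temperature",
                  "nucleic_acid_binding", "transporter", "metabolic"]


def load_lexicon(path=None) -> dict[str, list[re.Pattern]]:
    """Compile the keyword lexicon (default or from a YAML file)."""
    raw = yaml.safe_load(open(path).read() if path else DEFAULT_LEXICON_YAML)
    return {k: [re.compile(p, re.IGNORECASE) for p in v] for k, v in raw.items()}


def classify_product(product: str, lexicon=None) -> str:
    """Lexicon class of a gene-product string: a keyword class, other, or unknown."""
    if not product:
        return "unknown"
    lexicon = lexicon or load_lexicon()
    for key in _LEXICON_ORDER:
        for pat in lexicon.get(key, []):
            if pat.search(product):
                return key
    return "other"


@dataclass
class GeneContext:
    """Gene-neighborhood evidence aggregated over motif members."""

    downstream_same_strand_fraction: float = 0.0
    dominant_context_key: str = "unknown"
    dominant_gene_fraction: float = 0.0
    copies_per_genome_median: float = 0.0
    orientation_consistent: bool = True


@dataclass
class MotifEvidence:
    """Everything the rule engine consumes for one motif."""

    motif_id: str = ""
    n_total: int = 0
    n_unique: int = 0
    n_stems: int = 0
    n_covarying_pairs: int = 0
    n_conserved_cols_90: int = 0
    has_terminator: bool = False
    sd_overlaps_structure: bool = False
    uorf: sa.UorfCall | None = None
    sorf_like: bool = False
    context: GeneContext = field(default_factory=GeneContext)
    pseudoknot_note: bool = False


@dataclass
class RuleConfig:
    """Tunable thresholds of the rule engine."""

    mrsc_copies: int = 3
    src_stems: int = 3
    src_covary: int = 3
    hrc_covary: int = 3
    utr_fraction: float = 0.75
    max_utr_gap: int = 100
    lrc_max_unique: int = 5    # exclusive: "fewer than five"
    mrc_max_unique: int = 20
    hrc_conserved_cols: int = 10


def _downstream_gene(row, genome: Genome, max_gap: int):
    """Nearest same-strand CDS just downstream of an aligned member."""
    if row.strand == "+":
        best = None
        for f in genome.features:
            if f.kind != "CDS" or f.start < row.end:
                continue
            if best is None or f.start < best.start:
                best = f
        if best is not None and best.strand == "+" and best.start - row.end <= max_gap:
            return best
    else:
        best = None
        for f in genome.features:
            if f.kind != "CDS" or f.end > row.start:
                continue
            if best is None or f.end > best.end:
                best = f
        if best is not None and best.strand == "-" and row.start - best.end <= max_gap:
            return best
    return None


def extract_evidence(motif: MotifAlignment, genomes: list[Genome],
                     lexicon=None, cfg: RuleConfig | None = None) -> MotifEvidence:
    """Populate a MotifEvidence record from the alignment and its genomes.

    Requires the motif's structure analysis to have been run (``ss_cons``
    set); every row must resolve to a genome in *genomes*.
    """
    cfg = cfg or RuleConfig()
    lexicon = lexicon or load_lexicon()
    by_id = {g.genome_id: g for g in genomes}
    missing = [r.igr_id for r in motif.rows if r.genome_id not in by_id]
    if missing:
        raise KeyError(f"motif rows reference unknown genomes: {missing[:3]}")

    ss = motif.ss_cons or "." * motif.width
    profile = motif.column_stats or sa.conservation_profile(motif)
    cons_seq = "".join((cc.dominant_nt or "N") for cc in profile)
    pairs = ss_pairs(ss)
    n_cov = 0
    if pairs and len(motif.rows) >= sa.MIN_PAIR_ROWS:
        klass = sa.pair_class_matrix(motif)
        n_cov = int(sum(klass[i, j] == 2 for i, j in pairs))
    term = sa.find_terminator(cons_seq, fold=ss)

    downstream = []
    context_keys = []
    sd_overlap_votes = []
    per_genome: dict[str, int] = {}
    paired_cols = {i for p in pairs for i in p}
    for row in motif.rows:
        genome = by_id[row.genome_id]
        per_genome[row.genome_id] = per_genome.get(row.genome_id, 0) + 1
        gene = _downstream_gene(row, genome, cfg.max_utr_gap)
        if gene is None:
            continue
        downstream.append(row)
        context_keys.append(classify_product(gene.product, lexicon))
        paired_genome = _project_paired(row, motif, paired_cols)
        sd = sa.find_sd(_row_igr(row, genome), gene, genome_seq=genome.sequence,
                        paired_positions=paired_genome)
        sd_overlap_votes.append(bool(sd and sd.overlaps_structure))

    n_rows = len(motif.rows)
    frac_ds = len(downstream) / n_rows if n_rows else 0.0
    keyed = [k for k in context_keys if k != "unknown"]
    if keyed:
        best = max(set(keyed), key=lambda k: (keyed.count(k), k))
        dom_key, dom_frac = best, keyed.count(best) / len(context_keys)
    elif context_keys:
        dom_key, dom_frac = "unknown", 0.0
    else:
        dom_key, dom_frac = "unknown", 0.0
    copies = sorted(per_genome.values())
    median = copies[len(copies) // 2] if len(copies) % 2 else \
        0.5 * (copies[len(copies) // 2 - 1] + copies[len(copies) // 2])
    strands = {r.strand for r in motif.rows}

    uorf = sa.find_uorf(motif)
    context = GeneContext(
        downstream_same_strand_fraction=frac_ds,
        dominant_context_key=dom_key,
        dominant_gene_fraction=dom_frac,
        copies_per_genome_median=float(median) if copies else 0.0,
        orientation_consistent=(len(strands) == 1),
    )
    return MotifEvidence(
        motif_id=motif.motif_id,
        n_total=motif.n_total,
        n_unique=motif.n_unique,
        n_stems=sa.count_stems(ss),
        n_covarying_pairs=n_cov,
        n_conserved_cols_90=sum(1 for cc in profile if cc.level in ("n97", "n90")),
        has_terminator=term.is_terminator,
        sd_overlaps_structure=(bool(sd_overlap_votes)
                               and sum(sd_overlap_votes) / len(sd_overlap_votes) >= 0.5),
        uorf=uorf,
        sorf_like=bool(uorf and uorf.conserved) and frac_ds < cfg.utr_fraction,
        context=context,
        pseudoknot_note=sa.pseudoknot_note(motif, ss) if pairs else False,
    )


def _row_igr(row, genome) -> IGR:
    return IGR(igr_id=row.igr_id, genome_id=row.genome_id, start=row.start,
               end=row.end, sequence=genome.sequence[row.start:row.end])


def _project_paired(row, motif: MotifAlignment, paired_cols) -> set[int]:
    """Genome coordinates of this row's residues under paired columns."""
    out = set()
    p = 0
    n = row.end - row.start
    for c, ch in enumerate(row.seq):
        if ch in "-._~":
            continue
        if c in paired_cols:
            if row.strand == "+":
                out.add(row.start + p)
            else:
                out.add(row.end - 1 - p)
        p += 1
    if p != n:
        # row sequence and interval disagree; positions are best-effort
        pass
    return out


def classify(ev: MotifEvidence, cfg: RuleConfig | None = None) -> str:
    """Assign exactly one category; the first matching rule wins.

    Precedence: MRSC, uORFC, sORF, TSC, RLC, PBC, RTC, SRC, WRC, sRNA, then
    the rank fallback LRC / MRC / HRC / Unnamed.
    """
    cfg = cfg or RuleConfig()
    ctx = ev.context
    utr = ctx.downstream_same_strand_fraction >= cfg.utr_fraction

    if (ctx.copies_per_genome_median >= cfg.mrsc_copies
            or (not ctx.orientation_consistent
                and ctx.dominant_context_key == "transposase_like")):
        return "MRSC"
    if ev.uorf is not None and ev.uorf.conserved and utr:
        return "uORFC"
    if ev.sorf_like:
        return "sORF"
    if ev.n_stems == 1 and ev.has_terminator and ev.n_covarying_pairs >= 1:
        return "TSC"
    if utr and ctx.dominant_context_key == "ribosomal_protein":
        return "RLC"
    if utr and ctx.dominant_context_key == "nucleic_acid_binding":
        return "PBC"
    if utr and ctx.dominant_context_key == "temperature":
        return "RTC"
    if (utr and ctx.dominant_context_key in ("metabolic", "transporter")
            and ev.n_stems >= cfg.src_stems
            and ev.n_covarying_pairs >= cfg.src_covary
            and ctx.dominant_gene_fraction >= 0.75
            and (ev.has_terminator or ev.sd_overlaps_structure)):
        return "SRC"
    if (utr and ctx.dominant_context_key in ("metabolic", "transporter", "other")
            and ev.n_stems >= 2 and ev.n_covarying_pairs >= 1):
        return "WRC"
    if ctx.downstream_same_strand_fraction < 0.5 and ev.n_stems <= 1:
        return "sRNA"
    if ev.n_unique < cfg.lrc_max_unique:
        return "LRC"
    if ev.n_unique < cfg.mrc_max_unique:
        return "MRC"
    if (ev.n_covarying_pairs >= cfg.hrc_covary
            and ev.n_conserved_cols_90 >= cfg.hrc_conserved_cols):
        return "HRC"
    return "Unnamed"


# census rows, in the order of the published summary table
CENSUS_ROWS = [
    ("Known ORFs", None), ("Low-ranking candidates", "LRC"),
    ("Unnamed", "Unnamed"), ("Mobile/repeat sequence candidates", "MRSC"),
    ("Medium-ranking candidates", "MRC"), ("Protein-binding candidates", "PBC"),
    ("Known RNAs", None), ("High-ranking candidates", "HRC"),
    ("Terminator stems", "TSC"), ("Weak riboswitch candidates", "WRC"),
    ("Ribosomal leader candidates", "RLC"), ("Strong riboswitch candidates", "SRC"),
    ("sRNA candidates", "sRNA"), ("uORF candidates", "uORFC"),
    ("sORF candidates", "sORF"), ("RNA thermometer candidates", "RTC"),
    ("Other named candidates", "Other"),
]


def summarize(labels: list[tuple[str, str]], igr_statuses: list[str]):
    """Census DataFrame: counts per category plus Known ORFs/RNAs and Total.

    ``labels`` are (motif_id, category) pairs; "Known ORFs" and "Known RNAs"
    are counted from IGR statuses.  The "Other" row exists for override
    labels only; no rule produces it.
    """
    import pandas as pd
    by_cat: dict[str, int] = {}
    for _, cat in labels:
        by_cat[cat] = by_cat.get(cat, 0) + 1
    rows = []
    total = 0
    for name, cat in CENSUS_ROWS:
        if name == "Known ORFs":
            n = sum(1 for s in igr_statuses if s == "known_orf")
        elif name == "Known RNAs":
            n = sum(1 for s in igr_statuses if s == "known_rna")
        else:
            n = by_cat.get(cat, 0)
        rows.append((name, n))
        total += n
    rows.append(("Total", total))
    return pd.DataFrame(rows, columns=["Motif category", "Total counts"])


def report_motif(motif: MotifAlignment, ev: MotifEvidence, label: str,
                 genomes: list[Genome], outdir) -> None:
    """Per-motif report: annotated Stockholm, JSON evidence, gene TSV."""
    os.makedirs(outdir, exist_ok=True)
    profile = motif.column_stats or sa.conservation_profile(motif)
    level_digit = {"n97": "3", "n90": "2", "n75": "1", "present": "0", "variable": "."}
    motif.extra_gc.setdefault("cons", "".join((c.dominant_nt or ".") for c in profile))
    motif.extra_gc.setdefault("conss", "".join(level_digit[c.level] for c in profile))
    motif.gf.setdefault("CC", f"category={label}")
    write_stockholm(motif, os.path.join(outdir, f"{motif.motif_id}.sto"))
    payload = {
        "motif_id": motif.motif_id,
        "category": label,
        "n_total": ev.n_total,
        "n_unique": ev.n_unique,
        "n_stems": ev.n_stems,
        "n_covarying_pairs": ev.n_covarying_pairs,
        "n_conserved_cols_90": ev.n_conserved_cols_90,
        "has_terminator": ev.has_terminator,
        "sd_overlaps_structure": ev.sd_overlaps_structure,
        "uorf": (None if ev.uorf is None else
                 {"start_column": ev.uorf.start_column,
                  "stop_column": ev.uorf.stop_column,
                  "frame_consistent_fraction": ev.uorf.frame_consistent_fraction}),
        "sorf_like": ev.sorf_like,
        "pseudoknot_note": ev.pseudoknot_note,
        "context": {
            "downstream_same_strand_fraction": ev.context.downstream_same_strand_fraction,
            "dominant_context_key": ev.context.dominant_context_key,
            "dominant_gene_fraction": ev.context.dominant_gene_fraction,
            "copies_per_genome_median": ev.context.copies_per_genome_median,
            "orientation_consistent": ev.context.orientation_consistent,
        },
    }
    with open(os.path.join(outdir, f"{motif.motif_id}.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    by_id = {g.genome_id: g for g in genomes}
    cfg = RuleConfig()
    with open(os.path.join(outdir, f"{motif.motif_id}_genes.tsv"), "w") as fh:
        fh.write("igr_id\tgenome_id\tstrand\tdownstream_gene\tproduct\tcontext_class\n")
        for row in motif.rows:
            gene = _downstream_gene(row, by_id[row.genome_id], cfg.max_utr_gap)
            fh.write("\t".join([
                row.igr_id, row.genome_id, row.strand,
                gene.feature_id if gene else ".",
                gene.product if gene else ".",
                classify_product(gene.product) if gene else ".",
            ]) + "\n")
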