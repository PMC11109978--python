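"""Synthetic annotated genomes with planted structured-RNA families.

The generator emulates the statistical premise of GC/length-based IGR mining
in AT-rich bacteria: most intergenic regions are short and AT-rich, while the
minority that template structured ncRNAs are longer and GC-richer.  Each run
produces a cohort of annotated species genomes containing

* background protein-coding genes separated by short AT-rich IGRs,
* annotated known-RNA features (tRNA-like) inside GC-rich IGRs — the anchors
  the selection-region fit relies on,
* planted homologous motif families shared across species, with compensatory
  (covarying) substitutions in their stems,
* decoy IGRs: unannotated protein-coding ORFs and high-GC unstructured
  sequence, both of which land inside the selection region,

plus a machine-readable truth table so every downstream stage can be scored
without external data.

Homologs are substitution-only (no indels): homolog 0 is the ancestor, and
every other homolog differs by point substitutions at unconserved unpaired
columns plus compensatory canonical-pair swaps at paired columns.  All
sequences are stored as DNA (T, not U); display conversion happens in the
alignment layer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .genome_io import Genome, GeneFeature, pct_gc
from . import coding_filter

__all__ = [
    "MotifFamilySpec",
    "SyntheticTruth",
    "GeneratorConfig",
    "sample_motif_family",
    "generate_genomes",
    "write_outputs",
    "default_families",
]

CANONICAL_PAIRS = ["AT", "TA", "GC", "CG", "GT", "TG"]
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


class GenerationError(RuntimeError):
    pass


class CapacityError(RuntimeError):
    pass


# Sense codons whose third-position wobble cannot create a stop codon
# (first two bases never TA or TG), used for uORFs and decoy ORFs.
_SAFE_CODONS = [
    "GCT", "GCC", "GAA", "GAT", "CTG", "CTT", "ATT", "ATC", "GTT", "GTG",
    "AAA", "AAC", "GGT", "GGC", "CCG", "CCT", "TCT", "TCC", "CGT", "CGC",
]

_BACKGROUND_PRODUCTS = [
    "hypothetical protein",
    "membrane protein",
    "elongation factor Tu",
    "cell division protein FtsZ",
    "flagellar motor protein MotA",
    "outer membrane porin",
    "chemotaxis protein CheY",
    "septum site-determining protein",
    "peptidoglycan-associated lipoprotein",
    "S-layer homology domain protein",
]

# products handed to genes downstream of planted 5'-UTR motifs, keyed by the
# family's context class
CONTEXT_PRODUCTS = {
    "metabolic": ["acetolactate synthase large subunit", "gluconate 5-dehydrogenase"],
    "transporter": ["ABC transporter permease", "sodium:proline symporter"],
    "ribosomal_protein": ["30S ribosomal protein S4"],
    "nucleic_acid_binding": ["transcriptional regulator, MarR family", "DNA-binding protein HU"],
    "temperature": ["heat-shock protein chaperone"],
    "transposase_like": ["IS5 family transposase"],
}


@dataclass
class MotifFamilySpec:
    """Blueprint of one planted homologous motif family.

    ``loop_lengths`` interleaves unpaired regions with the hairpins:
    ``[flank0, loop1, flank1, loop2, ..., loopK, flankK]`` for K stems, so it
    must hold ``2 * n_stems + 1`` entries.  ``extras`` flags optional
    regulatory elements: ``terminator`` fixes the final flank to start with a
    six-U tail; ``uorf`` embeds an SD sequence plus a short conserved ORF in
    flank 0; ``sd_overlap`` writes an SD into the 3' side of the last stem.
    ``unpaired_alphabet`` restricts loop/flank composition ("CT" keeps
    unpaired regions pyrimidine, preventing them from pairing with U-tails).
    """

    family_id: str
    stem_lengths: list[int]
    loop_lengths: list[int]
    conserved_fraction: float = 0.55
    pair_covariation_rate: float = 0.3
    gc_bias: float = 55.0
    placement: str = "five_prime_utr"  # five_prime_utr | standalone | multicopy
    context_keyword: str = "other"
    extras: dict = field(default_factory=dict)
    sub_rate: float = 0.08
    unpaired_alphabet: str = "ACGT"
    stem_gc: float = 0.5  # 4-letter stem arms keep cross-species alignments in register

    @property
    def n_stems(self) -> int:
        return len(self.stem_lengths)

    @property
    def length(self) -> int:
        return 2 * sum(self.stem_lengths) + sum(self.loop_lengths)

    def __post_init__(self) -> None:
        if len(self.loop_lengths) != 2 * self.n_stems + 1:
            raise ValueError(f"{self.family_id}: loop_lengths must hold "
                             f"{2 * self.n_stems + 1} entries (flanks interleaved)")
        if not (0 <= self.gc_bias <= 100):
            raise ValueError("gc_bias must be a percentage")


def default_families() -> list[MotifFamilySpec]:
    """The five families of the "table1-bench" configuration.

    One family per category flavour: riboswitch-like (srcA), upstream-ORF
    (uorfA), terminator-stem (tscA), mobile/repeat (mrscA), and
    protein-binding leader (pbcA).
    """
    return [
        MotifFamilySpec(
            family_id="srcA", stem_lengths=[7, 7, 8],
            loop_lengths=[30, 8, 12, 8, 12, 4, 0],
            placement="five_prime_utr", context_keyword="transporter",
            extras={"sd_overlap": True}),
        MotifFamilySpec(
            family_id="uorfA", stem_lengths=[6],
            loop_lengths=[94, 4, 10],
            placement="five_prime_utr", context_keyword="metabolic",
            extras={"uorf": True}),
        MotifFamilySpec(
            family_id="tscA", stem_lengths=[8],
            loop_lengths=[100, 4, 8],
            placement="standalone", context_keyword="other",
            extras={"terminator": True}, unpaired_alphabet="CT"),
        MotifFamilySpec(
            family_id="mrscA", stem_lengths=[10],
            loop_lengths=[60, 6, 40],
            placement="multicopy", context_keyword="transposase_like"),
        MotifFamilySpec(
            family_id="pbcA", stem_lengths=[7, 7],
            loop_lengths=[42, 8, 20, 7, 18],
            placement="five_prime_utr", context_keyword="nucleic_acid_binding"),
    ]


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic benchmark ("table1-bench")."""

    n_species: int = 20
    background_gc: float = 35.0
    n_genes: int = 120
    gene_len_codons: tuple[int, int] = (100, 800)  # 300-2400 nt
    igr_len_lognorm: tuple[float, float] = (4.0, 0.5)
    igr_len_clip: tuple[int, int] = (20, 400)
    families: list[MotifFamilySpec] = field(default_factory=default_families)
    n_coding_decoys: int = 15
    n_highgc_decoys: int = 15
    n_known_rna: int = 8
    known_rna_gc: tuple[float, float] = (44.0, 54.0)
    known_rna_len: tuple[int, int] = (100, 180)
    highgc_gc: tuple[float, float] = (50.0, 58.0)
    highgc_len: tuple[int, int] = (130, 250)
    coding_gc: float = 50.0
    coding_orf_codons: int = 61
    gc_offset: float = 15.0
    min_planted_len: int = 120
    copies_per_genome: int = 4
    pad_len: int = 12

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        fams = [MotifFamilySpec(**f) for f in d.pop("families", [])]
        for key in ("gene_len_codons", "igr_len_lognorm", "igr_len_clip",
                    "known_rna_gc", "known_rna_len", "highgc_gc", "highgc_len"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(families=fams, **d)
        return cfg


@dataclass
class SyntheticTruth:
    """Ground truth for everything planted: one row per element.

    ``table`` columns: genome_id, start, end, strand, element_kind, family_id.
    ``families`` maps family_id to its ancestor sequence (DNA), shared true
    structure (dot-bracket), and spec.
    """

    rows: list[dict] = field(default_factory=list)
    families: dict = field(default_factory=dict)

    def add(self, genome_id, start, end, strand, kind, family_id=""):
        self.rows.append(dict(genome_id=genome_id, start=int(start), end=int(end),
                              strand=strand, element_kind=kind, family_id=family_id))

    @property
    def table(self):
        import pandas as pd
        cols = ["genome_id", "start", "end", "strand", "element_kind", "family_id"]
        return pd.DataFrame(self.rows, columns=cols)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# family sampling
# ---------------------------------------------------------------------------

def _layout(spec: MotifFamilySpec):
    """Region list [(kind, length, stem_index)] and the true pair list."""
    regions = []
    regions.append(("flank", spec.loop_lengths[0], -1))
    for s in range(spec.n_stems):
        regions.append(("stem5", spec.stem_lengths[s], s))
        regions.append(("loop", spec.loop_lengths[2 * s + 1], s))
        regions.append(("stem3", spec.stem_lengths[s], s))
        regions.append(("flank", spec.loop_lengths[2 * s + 2], s))
    pos = 0
    coords = []
    for kind, ln, idx in regions:
        coords.append((kind, pos, pos + ln, idx))
        pos += ln
    pairs = []
    for s in range(spec.n_stems):
        s5 = next(c for c in coords if c[0] == "stem5" and c[3] == s)
        s3 = next(c for c in coords if c[0] == "stem3" and c[3] == s)
        m = s5[2] - s5[1]
        for x in range(m):
            pairs.append((s5[1] + x, s3[2] - 1 - x))
    return coords, sorted(pairs)


def _structure_string(length: int, pairs) -> str:
    ss = ["."] * length
    for i, j in pairs:
        ss[i] = "<"
        ss[j] = ">"
    return "".join(ss)


def _unpaired_weights(spec: MotifFamilySpec) -> tuple[list[str], np.ndarray]:
    paired_nt = 2 * sum(spec.stem_lengths)
    unpaired_nt = sum(spec.loop_lengths)
    total = paired_nt + unpaired_nt
    gc_u = (spec.gc_bias / 100.0 * total - spec.stem_gc * paired_nt) / max(unpaired_nt, 1)
    gc_u = float(np.clip(gc_u, 0.15, 0.85))
    if spec.unpaired_alphabet == "CT":
        return ["C", "T"], np.array([gc_u, 1 - gc_u])
    return ["A", "C", "G", "T"], np.array([(1 - gc_u) / 2, gc_u / 2, gc_u / 2, (1 - gc_u) / 2])


def _sample_ancestor(spec, rng):
    """One ancestor draw: sequence, true pairs, conserved mask, pair list."""
    coords, pairs = _layout(spec)
    L = spec.length
    seq = [""] * L
    letters, weights = _unpaired_weights(spec)
    conserved = np.zeros(L, dtype=bool)
    fixed = np.zeros(L, dtype=bool)   # columns that must never mutate
    # unpaired content
    for kind, a, b, _ in coords:
        if kind in ("flank", "loop"):
            draw = rng.choice(letters, size=b - a, p=weights)
            for x, ch in zip(range(a, b), draw):
                seq[x] = str(ch)
            conserved[a:b] = rng.random(b - a) < spec.conserved_fraction
    # paired content
    pair_gc = spec.stem_gc
    p = np.array([(1 - pair_gc) / 2, (1 - pair_gc) / 2, pair_gc / 2, pair_gc / 2,
                  0.0, 0.0])
    pair_choice = rng.choice(len(CANONICAL_PAIRS), size=len(pairs), p=p / p.sum())
    covary_ok = np.ones(len(pairs), dtype=bool)
    for (i, j), c in zip(pairs, pair_choice):
        seq[i], seq[j] = CANONICAL_PAIRS[c][0], CANONICAL_PAIRS[c][1]
    # extras
    if spec.extras.get("terminator"):
        a, b = coords[-1][1], coords[-1][2]
        if b - a < 8:
            raise ValueError(f"{spec.family_id}: terminator needs a final flank >= 8 nt")
        tail = "TTTTTTCC"
        for x, ch in enumerate(tail):
            seq[a + x] = ch
        conserved[a:a + 8] = True
        fixed[a:a + 8] = True
    if spec.extras.get("uorf"):
        f0a, f0b = coords[0][1], coords[0][2]
        n_codons = 13
        block = "AGGAGG" + "".join(rng.choice(["A", "C", "T"], size=6)) + "ATG" + \
            "".join(rng.choice(_SAFE_CODONS, size=n_codons)) + "TAA"
        if f0b - f0a < len(block):
            raise ValueError(f"{spec.family_id}: flank0 too short for a uORF block")
        off = f0a + (f0b - f0a - len(block))  # abut the downstream end of flank0
        for x, ch in enumerate(block):
            seq[off + x] = ch
        # SD, spacer, start and stop invariant; codon wobble positions free
        conserved[off:off + len(block)] = True
        fixed[off:off + 12] = True            # SD + spacer
        fixed[off + 12:off + 15] = True       # ATG
        fixed[off + len(block) - 3:off + len(block)] = True  # TAA
        for ci in range(n_codons):
            w = off + 15 + 3 * ci + 2
            conserved[w] = False              # wobble mutates
    if spec.extras.get("sd_overlap"):
        # write AGGAGG into the tail of the last stem's 3' side, complementing
        # the 5' partners so pairing is preserved
        last3 = [c for c in coords if c[0] == "stem3"][-1]
        sd = "AGGAGG"
        if last3[2] - last3[1] < 6:
            raise ValueError(f"{spec.family_id}: last stem too short for sd_overlap")
        for x, ch in enumerate(sd):
            j = last3[2] - 6 + x
            seq[j] = ch
        for pi, (i, j) in enumerate(pairs):
            if last3[2] - 6 <= j < last3[2]:
                seq[i] = revcomp(seq[j])
                covary_ok[pi] = False
                fixed[i] = fixed[j] = True
    return "".join(seq), pairs, conserved, fixed, covary_ok


def sample_motif_family(spec: MotifFamilySpec, n_homologs: int,
                        rng_seed) -> list[tuple[str, str]]:
    """Sample *n_homologs* related sequences sharing one true structure.

    Homolog 0 is the ancestor.  Other homologs carry point substitutions at
    unconserved unpaired columns (rate ``spec.sub_rate``, uniform over the 3
    alternative bases) and compensatory swaps at paired columns (probability
    ``spec.pair_covariation_rate`` per pair per homolog, uniform over the 5
    other canonical pairs) — so a stem mutation on one side is matched on the
    other, emulating covariation.  Sequences are DNA; the realized ancestor
    %GC is held within +/-5 points of ``spec.gc_bias`` (resampled up to 1000
    times, then a GenerationError).  Returns ``[(sequence, dot_bracket)]``;
    the dot-bracket is identical for all homologs.
    """
    if n_homologs < 1:
        raise ValueError("n_homologs must be >= 1")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    for _attempt in range(1000):
        seq, pairs, conserved, fixed, covary_ok = _sample_ancestor(spec, rng)
        if abs(pct_gc(seq) - spec.gc_bias) > 5.0:
            continue
        if not _coding_safe(spec, seq):
            continue
        break
    else:
        raise GenerationError(f"{spec.family_id}: could not satisfy gc_bias="
                              f"{spec.gc_bias} within 1000 resamples")
    ss = _structure_string(spec.length, pairs)
    paired_cols = {i for p in pairs for i in p}
    mutable = [x for x in range(spec.length)
               if x not in paired_cols and not conserved[x] and not fixed[x]]
    out = [(seq, ss)]
    alphabet = "ACGT"
    for _h in range(1, n_homologs):
        s = list(seq)
        for x in mutable:
            if rng.random() < spec.sub_rate:
                s[x] = rng.choice([c for c in alphabet if c != seq[x]])
        for pi, (i, j) in enumerate(pairs):
            if covary_ok[pi] and rng.random() < spec.pair_covariation_rate:
                cur = seq[i] + seq[j]
                alt = [pr for pr in CANONICAL_PAIRS if pr != cur]
                new = alt[int(rng.integers(len(alt)))]
                s[i], s[j] = new[0], new[1]
        out.append(("".join(s), ss))
    return out


def _coding_safe(spec: MotifFamilySpec, seq: str) -> bool:
    """Reject ancestors that look protein-coding or carry stray conserved ATGs."""
    orfs = coding_filter.scan_orfs(seq)
    if any(o.has_start and o.has_stop and o.n_codons >= 40 for o in orfs):
        return False
    if not spec.extras.get("uorf") and "ATG" in seq:
        return False
    return True


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def _random_seq(rng, n: int, gc: float) -> str:
    g = gc / 100.0
    return "".join(rng.choice(["A", "C", "G", "T"],
                              size=n, p=[(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]))


def _gene_seq(rng, n_codons: int) -> str:
    body = "".join(rng.choice(_SAFE_CODONS, size=n_codons - 2))
    return "ATG" + body + "TAA"


def generate_genomes(config: GeneratorConfig, rng_seed: int):
    """Generate the synthetic cohort; returns ``(genomes, truth)``.

    Deterministic for a fixed ``(config, rng_seed)``: the same call yields
    byte-identical sequences and annotations.
    """
    rng = np.random.default_rng(rng_seed)
    truth = SyntheticTruth()

    utr_fams = [f for f in config.families if f.placement == "five_prime_utr"]
    standalone_fams = [f for f in config.families if f.placement == "standalone"]
    multi_fams = [f for f in config.families if f.placement == "multicopy"]

    homologs: dict[str, list[tuple[str, str]]] = {}
    for fam in config.families:
        n = config.n_species * (config.copies_per_genome if fam.placement == "multicopy" else 1)
        fam_draws = sample_motif_family(fam, n, rng)
        homologs[fam.family_id] = fam_draws
        truth.families[fam.family_id] = {
            "ancestor": fam_draws[0][0], "structure": fam_draws[0][1], "spec": fam,
        }

    n_multi = len(multi_fams) * config.copies_per_genome
    n_special = (len(utr_fams) + len(standalone_fams) + n_multi
                 + config.n_known_rna + config.n_coding_decoys + config.n_highgc_decoys)
    interior = config.n_genes - 1
    n_utr_pool = len(range(1, config.n_genes - 1, 3))
    if n_special > interior - 2 or len(utr_fams) > n_utr_pool:
        raise CapacityError(f"{n_special} planted elements exceed capacity of "
                            f"{config.n_genes} genes per genome")

    genomes = []
    for s in range(config.n_species):
        gid = f"syn{s:02d}"
        genomes.append(_assemble_genome(gid, s, config, rng, homologs, truth,
                                        utr_fams, standalone_fams, multi_fams))
    return genomes, truth


def _assemble_genome(gid, species_index, cfg, rng, homologs, truth,
                     utr_fams, standalone_fams, multi_fams):
    n = cfg.n_genes
    gene_codons = rng.integers(cfg.gene_len_codons[0], cfg.gene_len_codons[1] + 1, size=n)
    gene_strands = np.where(rng.random(n) < 0.5, "+", "-")
    gene_products = [_BACKGROUND_PRODUCTS[int(i)]
                     for i in rng.integers(len(_BACKGROUND_PRODUCTS), size=n)]

    # slot assignment: IGR k (1..n-1) sits between gene k-1 and gene k.
    # 5'-UTR hosts draw from a strided pool so two hosts never share a gene.
    utr_pool = list(range(1, n - 1, 3))
    rng.shuffle(utr_pool)
    utr_slots = {fam.family_id: utr_pool[i] for i, fam in enumerate(utr_fams)}
    taken = set(utr_slots.values())
    free = [k for k in range(1, n) if k not in taken]
    rng.shuffle(free)
    it = iter(free)

    def take(count):
        return [next(it) for _ in range(count)]

    standalone_slots = {fam.family_id: take(1)[0] for fam in standalone_fams}
    multi_slots = {fam.family_id: take(cfg.copies_per_genome) for fam in multi_fams}
    known_slots = take(cfg.n_known_rna)
    coding_slots = take(cfg.n_coding_decoys)
    highgc_slots = take(cfg.n_highgc_decoys)

    # planted IGR content, keyed by slot: (sequence, builder-callback)
    special: dict[int, dict] = {}

    def planted_igr(fam, inst_seq, utr, strand):
        """The motif (+ gap to the gene) on the motif strand, oriented forward.

        The motif occupies its whole IGR — homologous end to end across
        species, as real structured-RNA IGRs often are — so cross-species
        alignments stay in register.  5'-UTR placements get an SD in the gap
        unless the family sequesters its own SD inside the structure, in
        which case the gap is short and purine-free so the in-stem SD is the
        one in the ribosome's scan window.
        """
        for _ in range(60):
            if utr and fam.extras.get("sd_overlap"):
                gap = "".join(rng.choice(["C", "T"], size=6, p=[0.5, 0.5]))
            elif utr:
                gap = "AGGAGG" + _random_seq(rng, 6, 40.0)
            else:
                gap = ""
            plus = inst_seq + gap
            if (pct_gc(plus) >= cfg.background_gc + cfg.gc_offset
                    and len(plus) >= cfg.min_planted_len):
                break
        seq = plus if strand == "+" else revcomp(plus)
        off = 0 if strand == "+" else len(gap)
        return seq, off, len(inst_seq)

    for fam in utr_fams:
        k = utr_slots[fam.family_id]
        inst = homologs[fam.family_id][species_index][0]
        strand = "+" if rng.random() < 0.5 else "-"
        seq, off, mlen = planted_igr(fam, inst, True, strand)
        host = k if strand == "+" else k - 1
        gene_strands[host] = strand
        prods = CONTEXT_PRODUCTS[fam.context_keyword]
        gene_products[host] = prods[int(rng.integers(len(prods)))]
        special[k] = dict(seq=seq, kind=f"ncRNA_family:{fam.family_id}",
                          fam=fam.family_id, off=off, mlen=mlen, strand=strand)

    for fam in standalone_fams:
        k = standalone_slots[fam.family_id]
        inst = homologs[fam.family_id][species_index][0]
        strand = "+" if rng.random() < 0.5 else "-"
        seq, off, mlen = planted_igr(fam, inst, False, strand)
        special[k] = dict(seq=seq, kind=f"ncRNA_family:{fam.family_id}",
                          fam=fam.family_id, off=off, mlen=mlen, strand=strand)

    for fam in multi_fams:
        for c, k in enumerate(multi_slots[fam.family_id]):
            inst = homologs[fam.family_id][species_index * cfg.copies_per_genome + c][0]
            strand = "+" if rng.random() < 0.5 else "-"
            seq, off, mlen = planted_igr(fam, inst, False, strand)
            special[k] = dict(seq=seq, kind=f"ncRNA_family:{fam.family_id}",
                              fam=fam.family_id, off=off, mlen=mlen, strand=strand)
            if c == 0:
                # flag one neighbour per genome as a transposase gene
                gene_products[k if k < cfg.n_genes else k - 1] = \
                    CONTEXT_PRODUCTS["transposase_like"][0]

    for k in known_slots:
        L = int(rng.integers(cfg.known_rna_len[0], cfg.known_rna_len[1] + 1))
        gc = float(rng.uniform(*cfg.known_rna_gc))
        seq = _random_seq(rng, L, gc)
        a = int(0.15 * L)
        b = a + int(0.7 * L)
        special[k] = dict(seq=seq, kind="known_rna", rna_span=(a, b))

    for k in coding_slots:
        nc = cfg.coding_orf_codons
        orf = "ATG" + "".join(rng.choice(_SAFE_CODONS, size=nc - 2)) + "TAA"
        pads = (_random_seq(rng, int(rng.integers(10, 41)), cfg.coding_gc),
                _random_seq(rng, int(rng.integers(10, 41)), cfg.coding_gc))
        body = orf if rng.random() < 0.5 else revcomp(orf)
        special[k] = dict(seq=pads[0] + body + pads[1], kind="coding_igr")

    for k in highgc_slots:
        L = int(rng.integers(cfg.highgc_len[0], cfg.highgc_len[1] + 1))
        gc = float(rng.uniform(*cfg.highgc_gc))
        special[k] = dict(seq=_random_seq(rng, L, gc), kind="high_gc_decoy")

    # assemble: igr_0 gene_0 igr_1 gene_1 ... gene_{n-1} igr_n
    mu, sigma = cfg.igr_len_lognorm
    parts: list[str] = []
    feats: list[GeneFeature] = []
    pos = 0
    for k in range(n + 1):
        if k in special:
            sp = special[k]
            seq = sp["seq"]
            if sp["kind"] == "known_rna":
                a, b = sp["rna_span"]
                feats.append(GeneFeature(f"{gid}_rna{k:04d}", pos + a, pos + b,
                                         "+" if rng.random() < 0.5 else "-",
                                         "known_rna", "tRNA-Ala"))
                truth.add(gid, pos + a, pos + b, "+", "known_rna")
            elif sp["kind"].startswith("ncRNA_family"):
                truth.add(gid, pos + sp["off"], pos + sp["off"] + sp["mlen"],
                          sp["strand"], sp["kind"], sp["fam"])
            else:
                truth.add(gid, pos, pos + len(seq), "+", sp["kind"])
        else:
            L = int(np.clip(rng.lognormal(mu, sigma), *cfg.igr_len_clip))
            seq = _random_seq(rng, L, cfg.background_gc)
        parts.append(seq)
        pos += len(seq)
        if k < n:
            g = _gene_seq(rng, int(gene_codons[k]))
            if gene_strands[k] == "-":
                g = revcomp(g)
            feats.append(GeneFeature(f"{gid}_g{k:04d}", pos, pos + len(g),
                                     str(gene_strands[k]), "CDS", gene_products[k]))
            parts.append(g)
            pos += len(g)
    return Genome(genome_id=gid, species_tag=gid, sequence="".join(parts),
                  features=feats, circular=False)


# ---------------------------------------------------------------------------
# truth-table evaluation of a pipeline run
# ---------------------------------------------------------------------------

# category (or categories) each benchmark family is built to exemplify
INTENDED_CATEGORIES = {
    "srcA": {"SRC", "WRC"},
    "uorfA": {"uORFC"},
    "tscA": {"TSC"},
    "mrscA": {"MRSC"},
    "pbcA": {"PBC"},
}


def _planted_rows(truth: SyntheticTruth):
    return [r for r in truth.rows if r["element_kind"].startswith("ncRNA_family:")]


def score_selection_recovery(igrs, region, truth: SyntheticTruth) -> float:
    """Fraction of planted ncRNA IGRs inside the fitted selection region."""
    by_genome: dict[str, list] = {}
    for igr in igrs:
        by_genome.setdefault(igr.genome_id, []).append(igr)
    planted = _planted_rows(truth)
    inside = 0
    for row in planted:
        for igr in by_genome.get(row["genome_id"], []):
            if igr.start <= row["start"] and row["end"] <= igr.end:
                if region.contains(igr.pct_gc, igr.length_nt):
                    inside += 1
                break
    return inside / len(planted) if planted else float("nan")


def _instances_by_family(truth):
    fams: dict[str, list] = {}
    for row in _planted_rows(truth):
        fid = row["element_kind"].split(":", 1)[1]
        fams.setdefault(fid, []).append(row)
    return fams


def _motif_of_instance(row, motifs):
    for m in motifs:
        for r in m.rows:
            if r.genome_id == row["genome_id"] and r.start <= row["start"] \
                    and row["end"] <= r.end:
                return m
    return None


def score_cluster_recovery(motifs, truth: SyntheticTruth) -> dict[str, float]:
    """Per family: largest fraction of its instances captured by one motif."""
    out = {}
    for fid, rows in _instances_by_family(truth).items():
        counts: dict[str, int] = {}
        for row in rows:
            m = _motif_of_instance(row, motifs)
            if m is not None:
                counts[m.motif_id] = counts.get(m.motif_id, 0) + 1
        out[fid] = max(counts.values()) / len(rows) if counts else 0.0
    return out


def score_basepair_recovery(motifs, genomes, truth: SyntheticTruth,
                            min_covariation_rate: float = 0.3) -> dict[str, float]:
    """Per family: fraction of true planted base pairs present in SS_cons.

    True pairs are mapped from motif-local coordinates to alignment columns
    per row (strand-aware, via exact location of the planted instance inside
    the row) and the majority column pair is compared with the consensus
    structure.  Families below *min_covariation_rate* are skipped: without
    compensatory variation, structure recovery is not expected.
    """
    from collections import Counter
    from .genome_io import ss_pairs
    gseq = {g.genome_id: g.sequence for g in genomes}
    out = {}
    for fid, rows in _instances_by_family(truth).items():
        fam = truth.families[fid]["spec"]
        if fam.pair_covariation_rate < min_covariation_rate:
            continue
        ss_true = truth.families[fid]["structure"]
        true_local = ss_pairs(ss_true.replace("<", "(").replace(">", ")"))
        if not true_local:
            continue
        # majority motif
        counts: dict[str, int] = {}
        for row in rows:
            m = _motif_of_instance(row, motifs)
            if m is not None:
                counts[m.motif_id] = counts.get(m.motif_id, 0) + 1
        if not counts:
            out[fid] = 0.0
            continue
        motif = next(m for m in motifs
                     if m.motif_id == max(counts, key=lambda k: (counts[k], k)))
        votes: Counter = Counter()
        for row in rows:
            mrow = next((r for r in motif.rows
                         if r.genome_id == row["genome_id"]
                         and r.start <= row["start"] and row["end"] <= r.end), None)
            if mrow is None:
                continue
            inst = gseq[row["genome_id"]][row["start"]:row["end"]]
            inst = inst if row["strand"] == "+" else revcomp(inst)
            ung = mrow.seq.replace("-", "").replace(".", "").replace("U", "T")
            cols = [c for c, ch in enumerate(mrow.seq) if ch not in "-._~"]
            L = len(inst)
            if inst in ung:
                u0 = ung.index(inst)
                for i, j in true_local:
                    votes[(cols[u0 + i], cols[u0 + j])] += 1
            elif revcomp(inst) in ung:
                u0 = ung.index(revcomp(inst))
                for i, j in true_local:
                    votes[tuple(sorted((cols[u0 + L - 1 - i],
                                        cols[u0 + L - 1 - j])))] += 1
        fold_pairs = set(ss_pairs(motif.ss_cons or ""))
        mapped = [p for p, _ in votes.most_common(len(true_local))]
        hit = sum(1 for p in mapped if p in fold_pairs)
        out[fid] = hit / len(true_local)
    return out


def score_category_accuracy(motifs, labels, truth: SyntheticTruth,
                            intended: dict | None = None) -> dict[str, bool]:
    """Per family: did its majority motif receive an intended category."""
    intended = intended or INTENDED_CATEGORIES
    by_id = dict(labels)
    out = {}
    for fid, rows in _instances_by_family(truth).items():
        counts: dict[str, int] = {}
        for row in rows:
            m = _motif_of_instance(row, motifs)
            if m is not None:
                counts[m.motif_id] = counts.get(m.motif_id, 0) + 1
        if not counts:
            out[fid] = False
            continue
        mid = max(counts, key=lambda k: (counts[k], k))
        out[fid] = by_id.get(mid) in intended.get(fid, set())
    return out


def write_outputs(genomes, truth: SyntheticTruth, config: GeneratorConfig, outdir) -> None:
    """Per-species FASTA + GFF3, truth TSV, and the generator config as YAML."""
    import os
    from .genome_io import write_gff3_fasta
    os.makedirs(outdir, exist_ok=True)
    for g in genomes:
        write_gff3_fasta(g, os.path.join(outdir, f"{g.genome_id}.gff3"),
                         os.path.join(outdir, f"{g.genome_id}.fna"))
    truth.to_tsv(os.path.join(outdir, "truth.tsv"))
    config.to_yaml(os.path.join(outdir, "config.yaml"))
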