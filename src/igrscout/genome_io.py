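"""Genome and alignment I/O.

Reads annotated bacterial replicons (GenBank flat files or GFF3+FASTA pairs),
extracts intergenic regions (IGRs) with flanking-gene context, and exchanges
motif alignments as Stockholm 1.0 with consensus-structure annotation.

Coordinate convention: everything internal is 0-based, half-open, with strands
"+" and "-".  GenBank and GFF3 (1-based inclusive) are converted at the
boundary.  A wrap-around IGR on a circular replicon is stored with
``end > len(sequence)``; its sequence is the concatenation of the 3' and 5'
arcs, so ``length_nt == end - start`` still holds.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "Genome",
    "GeneFeature",
    "IGR",
    "MotifRow",
    "MotifAlignment",
    "read_annotated_genome",
    "extract_igrs",
    "read_stockholm",
    "write_stockholm",
    "pct_gc",
    "ss_pairs",
]

# GenBank / GFF3 feature types treated as annotated structured RNAs.  An IGR
# overlapping one of these is labelled "known_rna" and excluded from candidate
# selection (but it anchors the selection-region fit).
KNOWN_RNA_KINDS = {
    "tRNA", "rRNA", "ncRNA", "tmRNA", "misc_RNA", "riboswitch",
    "SRP_RNA", "RNase_P_RNA", "antisense_RNA",
}
_SKIP_KINDS = {"gene", "source", "region", "chromosome", "exon", "mRNA"}

_MIN_LEN_DEFAULT = 25


class ParseError(ValueError):
    """Malformed input file."""


class ConsistencyError(ValueError):
    """Sequence / annotation identifiers do not agree."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on a replicon (0-based half-open interval)."""

    feature_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    kind: str  # "CDS", "known_rna", or "other"
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad feature interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ParseError(f"feature {self.feature_id}: unknown strand {self.strand!r}")


@dataclass
class Genome:
    """One annotated replicon: sequence plus strand-aware gene features."""

    genome_id: str
    species_tag: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise ValueError(f"feature {f.feature_id} exceeds sequence length {n}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class IGR:
    """An intergenic interval: the pipeline's unit of selection.

    ``status`` moves through the pipeline: unknown -> candidate (selected) or
    known_rna / known_orf (removed).  ``end > len(genome)`` marks a
    wrap-around interval on a circular replicon.
    """

    igr_id: str
    genome_id: str
    start: int
    end: int
    sequence: str
    left_gene: GeneFeature | None = None
    right_gene: GeneFeature | None = None
    status: str = "unknown"

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("IGR length inconsistent with its interval")

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def pct_gc(self) -> float:
        return pct_gc(self.sequence)


def pct_gc(sequence: str) -> float:
    """Percent G+C among unambiguous bases of *sequence*.

    N and other ambiguity codes are excluded from numerator and denominator.
    Returns ``nan`` when no unambiguous base is present.  Empty input is a
    domain error.
    """
    if not sequence:
        raise ValueError("pct_gc of empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    total = gc + s.count("A") + s.count("T") + s.count("U")
    if total == 0:
        return float("nan")
    return 100.0 * gc / total


# ---------------------------------------------------------------------------
# reading annotated genomes
# ---------------------------------------------------------------------------

def _classify_kind(ftype: str) -> str | None:
    if ftype == "CDS":
        return "CDS"
    if ftype in KNOWN_RNA_KINDS:
        return "known_rna"
    if ftype in _SKIP_KINDS:
        return None
    return "other"


def read_annotated_genome(
    path: str | os.PathLike,
    format: str = "genbank",
    fasta_path: str | os.PathLike | None = None,
    species_tag: str | None = None,
) -> Genome:
    """Read one annotated replicon from ``genbank`` or ``gff3+fasta``.

    For ``gff3+fasta``, *path* names the GFF3 file; *fasta_path* defaults to
    the same stem with a ``.fna``/``.fa``/``.fasta`` extension.  GFF3 1-based
    inclusive coordinates become 0-based half-open.  Features with unknown
    strand are rejected; a FASTA/GFF3 identifier mismatch is a consistency
    error.
    """
    if format == "genbank":
        return _read_genbank(path, species_tag)
    if format == "gff3+fasta":
        return _read_gff3_fasta(path, fasta_path, species_tag)
    raise ValueError(f"unknown format {format!r}")


def _read_genbank(path, species_tag):
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # biopython raises bare ValueError on bad records
        raise ParseError(f"{path}: not a readable GenBank record ({exc})") from exc
    feats: list[GeneFeature] = []
    for i, f in enumerate(record.features):
        kind = _classify_kind(f.type)
        if kind is None:
            continue
        if f.location is None or f.location.strand not in (1, -1):
            raise ParseError(f"{path}: feature #{i} ({f.type}) has unknown strand")
        product = ""
        for key in ("product", "note", "gene"):
            if key in f.qualifiers:
                product = f.qualifiers[key][0]
                break
        fid = f.qualifiers.get("locus_tag", [f"{f.type}_{i}"])[0]
        feats.append(GeneFeature(
            feature_id=fid,
            start=int(f.location.start),
            end=int(f.location.end),
            strand="+" if f.location.strand == 1 else "-",
            kind=kind,
            product=product,
        ))
    topology = record.annotations.get("topology", "linear")
    organism = record.annotations.get("organism", "") or record.id
    return Genome(
        genome_id=record.id,
        species_tag=species_tag or organism,
        sequence=str(record.seq),
        features=feats,
        circular=(topology == "circular"),
    )


_GFF_ATTR = re.compile(r"([^=;]+)=([^;]*)")


def _read_gff3_fasta(path, fasta_path, species_tag):
    rows = []
    fasta_block: list[str] = []
    seen_fasta = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if seen_fasta:
                fasta_block.append(line)
                continue
            if line.startswith("##FASTA"):
                seen_fasta = True
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns")
            rows.append((lineno, parts))

    if fasta_block:
        seqs = {r.id: str(r.seq) for r in SeqIO.parse(io.StringIO("\n".join(fasta_block)), "fasta")}
    else:
        if fasta_path is None:
            stem = os.path.splitext(str(path))[0]
            for ext in (".fna", ".fa", ".fasta"):
                if os.path.exists(stem + ext):
                    fasta_path = stem + ext
                    break
            else:
                raise ParseError(f"{path}: no companion FASTA found for GFF3")
        seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise ParseError(f"{path}: FASTA companion holds no sequences")

    seqids = {p[0] for _, p in rows}
    unknown = seqids - set(seqs)
    if unknown:
        raise ConsistencyError(f"{path}: GFF3 seqids {sorted(unknown)} absent from FASTA")
    if len(seqs) > 1 and not seqids.issuperset(seqs):
        orphans = sorted(set(seqs) - seqids)
        raise ConsistencyError(f"{path}: FASTA records {orphans} absent from GFF3")

    seqid = sorted(seqs)[0] if not seqids else sorted(seqids)[0]
    circular = False
    feats: list[GeneFeature] = []
    for lineno, p in rows:
        _, _, ftype, start, end, _, strand, _, attrs = p
        kind = _classify_kind(ftype)
        if ftype == "region":
            circular = circular or "Is_circular=true" in attrs
        if kind is None:
            continue
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: feature with unknown strand {strand!r}")
        attr = dict(_GFF_ATTR.findall(attrs))
        feats.append(GeneFeature(
            feature_id=attr.get("ID", f"{ftype}_{lineno}"),
            start=int(start) - 1,  # 1-based inclusive -> 0-based half-open
            end=int(end),
            strand=strand,
            kind=kind,
            product=attr.get("product", attr.get("Name", "")),
        ))
    return Genome(
        genome_id=seqid,
        species_tag=species_tag or seqid,
        sequence=seqs[seqid],
        features=feats,
        circular=circular,
    )


def write_gff3_fasta(genome: Genome, gff_path, fasta_path) -> None:
    """Write a Genome back out as a GFF3 + FASTA pair (inverse of reading)."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.genome_id} 1 {len(genome)}\n")
        if genome.circular:
            fh.write(f"{genome.genome_id}\tigrscout\tregion\t1\t{len(genome)}\t.\t+\t.\t"
                     f"ID=region0;Is_circular=true\n")
        type_of = {"CDS": "CDS", "known_rna": "ncRNA", "other": "misc_feature"}
        for f in genome.features:
            attrs = f"ID={f.feature_id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(f"{genome.genome_id}\tigrscout\t{type_of[f.kind]}\t"
                     f"{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n")
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.genome_id}\n")
        for i in range(0, len(genome.sequence), 70):
            fh.write(genome.sequence[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# intergenic-region extraction
# ---------------------------------------------------------------------------

def extract_igrs(genome: Genome, min_len: int = _MIN_LEN_DEFAULT) -> list[IGR]:
    """Extract maximal gaps between protein-coding genes as IGRs.

    Only CDS features bound IGRs; an annotated RNA feature does not split an
    IGR but marks any overlapping IGR ``status="known_rna"`` (those IGRs are
    the known points used later to fit the selection region).  "other"
    features never break an IGR.  On circular replicons the gap between the
    last and first CDS wraps around the origin.
    """
    if not genome.features:
        raise ValueError("genome has no features")
    cds = [f for f in genome.features if f.kind == "CDS"]
    rnas = [f for f in genome.features if f.kind == "known_rna"]
    n = len(genome)
    igrs: list[IGR] = []

    def emit(start: int, end: int, left: GeneFeature | None, right: GeneFeature | None):
        if end - start < min_len:
            return
        if end <= n:
            seq = genome.sequence[start:end]
            spans = [(start, end)]
        else:  # wrap-around
            seq = genome.sequence[start:] + genome.sequence[: end - n]
            spans = [(start, n), (0, end - n)]
        status = "unknown"
        for r in rnas:
            if any(r.start < e and s < r.end for s, e in spans):
                status = "known_rna"
                break
        igrs.append(IGR(
            igr_id=f"{genome.genome_id}|igr{start:07d}",
            genome_id=genome.genome_id,
            start=start, end=end, sequence=seq,
            left_gene=left, right_gene=right, status=status,
        ))

    if not cds:
        emit(0, n, None, None)
        return igrs

    # merge overlapping CDS into a running boundary
    prev = cds[0]
    prev_end = prev.start  # handled below for the leading gap
    if genome.circular:
        last = cds[-1]
        if last.end < n or cds[0].start > 0:
            emit(last.end, n + cds[0].start, last, cds[0])
    else:
        if cds[0].start >= min_len:
            emit(0, cds[0].start, None, cds[0])
    prev = cds[0]
    prev_end = cds[0].end
    for f in cds[1:]:
        if f.start > prev_end:
            emit(prev_end, f.start, prev, f)
        if f.end >= prev_end:
            prev, prev_end = f, f.end
    if not genome.circular and prev_end < n:
        emit(prev_end, n, prev, None)
    igrs.sort(key=lambda g: g.start)
    return igrs


# ---------------------------------------------------------------------------
# secondary-structure string utilities
# ---------------------------------------------------------------------------

_OPEN = "<([{"
_CLOSE = ">)]}"
_PAIR_OF = dict(zip(_CLOSE, _OPEN))


def ss_pairs(ss: str) -> list[tuple[int, int]]:
    """Base pairs (i, j), i<j, from a dot-bracket / WUSS string.

    Each bracket family nests independently; letters and ``.,_-:~`` are
    unpaired.  Raises ``ValueError`` on unbalanced brackets.
    """
    stacks: dict[str, list[int]] = {c: [] for c in _OPEN}
    pairs = []
    for i, ch in enumerate(ss):
        if ch in _OPEN:
            stacks[ch].append(i)
        elif ch in _CLOSE:
            st = stacks[_PAIR_OF[ch]]
            if not st:
                raise ValueError(f"unbalanced structure string at column {i}")
            pairs.append((st.pop(), i))
    for st in stacks.values():
        if st:
            raise ValueError("unbalanced structure string: unclosed bracket")
    return sorted(pairs)


# ---------------------------------------------------------------------------
# motif alignments and Stockholm exchange
# ---------------------------------------------------------------------------

@dataclass
class MotifRow:
    """One aligned homolog: where it came from and its gapped sequence."""

    igr_id: str
    genome_id: str
    start: int  # genome coordinates of the ungapped subsequence
    end: int
    strand: str
    seq: str  # gapped, RNA alphabet in display (T stored as U)


@dataclass
class MotifAlignment:
    """A gapped alignment of homologous IGR subsequences.

    ``ss_cons`` is the consensus secondary structure over alignment columns;
    ``column_stats`` (filled by the structure-analysis stage) carries one
    ConservationClass per column.  ``extra_gc`` / ``gf`` hold additional
    ``#=GC`` / ``#=GF`` annotation lines for Stockholm round-tripping.
    """

    motif_id: str
    rows: list[MotifRow]
    ss_cons: str | None = None
    column_stats: list | None = None
    extra_gc: dict[str, str] = field(default_factory=dict)
    gf: dict[str, str] = field(default_factory=dict)

    @property
    def width(self) -> int:
        return len(self.rows[0].seq) if self.rows else 0

    @property
    def n_total(self) -> int:
        return len(self.rows)

    @property
    def n_unique(self) -> int:
        return len({r.seq.replace("-", "").replace(".", "").upper().replace("T", "U")
                    for r in self.rows})

    def validate(self) -> None:
        if not self.rows:
            raise ValueError(f"motif {self.motif_id}: empty alignment")
        w = self.width
        if any(len(r.seq) != w for r in self.rows):
            raise ValueError(f"motif {self.motif_id}: ragged alignment")
        if self.ss_cons is not None:
            if len(self.ss_cons) != w:
                raise ValueError(f"motif {self.motif_id}: SS_cons width mismatch")
            ss_pairs(self.ss_cons)  # raises on imbalance

    def ungapped(self) -> list[str]:
        return [r.seq.replace("-", "").replace(".", "") for r in self.rows]


def _row_name(row: MotifRow) -> str:
    return f"{row.igr_id}/{row.start}-{row.end}"


_NAME_RE = re.compile(r"^(?P<igr>.+)/(?P<start>\d+)-(?P<end>\d+)$")


def write_stockholm(aln: MotifAlignment, path) -> None:
    """Write a MotifAlignment as Stockholm 1.0.

    Emits ``#=GF`` metadata, ``#=GS <seq> DE`` tags carrying genome id and
    strand, the aligned rows, extra ``#=GC`` per-column lines and
    ``#=GC SS_cons``.  Output is deterministic, so rewriting a freshly read
    file is byte-stable.
    """
    aln.validate()
    names = [_row_name(r) for r in aln.rows]
    pad = max(len(n) for n in names + [f"#=GC {k}" for k in
                                       list(aln.extra_gc) + ["SS_cons"]]) + 2
    with open(path, "w", newline="\n") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        fh.write(f"#=GF ID {aln.motif_id}\n")
        for k in sorted(aln.gf):
            fh.write(f"#=GF {k} {aln.gf[k]}\n")
        for name, row in zip(names, aln.rows):
            fh.write(f"#=GS {name} DE genome={row.genome_id} strand={row.strand}\n")
        for name, row in zip(names, aln.rows):
            fh.write(f"{name.ljust(pad)}{row.seq}\n")
        for k in sorted(aln.extra_gc):
            fh.write(f"{('#=GC ' + k).ljust(pad)}{aln.extra_gc[k]}\n")
        if aln.ss_cons is not None:
            fh.write(f"{'#=GC SS_cons'.ljust(pad)}{aln.ss_cons}\n")
        fh.write("//\n")


def read_stockholm(path) -> MotifAlignment:
    """Read one Stockholm alignment written by :func:`write_stockholm`."""
    motif_id = os.path.splitext(os.path.basename(str(path)))[0]
    gf: dict[str, str] = {}
    gs: dict[str, dict[str, str]] = {}
    seqs: dict[str, str] = {}
    order: list[str] = []
    gc: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# STOCKHOLM"):
            raise ParseError(f"{path}: not a Stockholm file")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line or line == "//":
                continue
            if line.startswith("#=GF"):
                _, key, val = line.split(None, 2)
                if key == "ID":
                    motif_id = val
                else:
                    gf[key] = val
            elif line.startswith("#=GS"):
                _, name, tag, val = line.split(None, 3)
                gs.setdefault(name, {})[tag] = val
            elif line.startswith("#=GC"):
                _, key, val = line.split(None, 2)
                gc[key] = gc.get(key, "") + val
            elif line.startswith("#"):
                continue
            else:
                parts = line.split()
                if len(parts) != 2:
                    raise ParseError(f"{path}:{lineno}: bad sequence line")
                name, chunk = parts
                if name not in seqs:
                    order.append(name)
                    seqs[name] = ""
                seqs[name] += chunk
    if not seqs:
        raise ParseError(f"{path}: alignment holds no sequences")
    widths = {len(s) for s in seqs.values()}
    if len(widths) != 1:
        raise ParseError(f"{path}: ragged alignment")
    rows = []
    for name in order:
        m = _NAME_RE.match(name)
        if not m:
            raise ParseError(f"{path}: unparseable sequence name {name!r}")
        meta = dict(_GFF_ATTR.findall(gs.get(name, {}).get("DE", "").replace(" ", ";")))
        rows.append(MotifRow(
            igr_id=m.group("igr"),
            genome_id=meta.get("genome", m.group("igr").split("|")[0]),
            start=int(m.group("start")),
            end=int(m.group("end")),
            strand=meta.get("strand", "+"),
            seq=seqs[name],
        ))
    ss = gc.pop("SS_cons", None)
    aln = MotifAlignment(motif_id=motif_id, rows=rows, ss_cons=ss, extra_gc=gc, gf=gf)
    aln.validate()
    return aln
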