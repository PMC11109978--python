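"""Removal of candidate IGRs that likely encode protein.

A desk-scale stand-in for a translated homology screen: candidate IGRs whose
longest complete open reading frame (bacterial genetic code, alternative
starts GTG/TTG) reaches ``min_codons`` are flagged ``known_orf`` and dropped.
An adapter hook (:class:`ExternalProteinSearch`) lets a real protein-database
search take precedence where one is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

from .genome_io import IGR

__all__ = ["OrfCall", "scan_orfs", "flag_coding", "ExternalProteinSearch",
           "parse_protein_search_tsv"]

START_CODONS = {"ATG", "GTG", "TTG"}
STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass(frozen=True)
class OrfCall:
    """A maximal open reading frame in IGR-local forward coordinates.

    The interval runs from the start codon through the stop codon inclusive;
    ``n_codons = (end - start) / 3`` therefore counts the stop codon when one
    is present.  ``frame`` is the frame index (0-2) on the ORF's own strand.
    """

    strand: str
    frame: int
    start: int
    end: int
    n_codons: int
    has_start: bool
    has_stop: bool


def _scan_strand(seq: str, strand: str) -> list[OrfCall]:
    n = len(seq)
    calls = []
    for frame in range(3):
        start_at: int | None = None
        for p in range(frame, n - 2, 3):
            codon = seq[p:p + 3]
            if "N" in codon:
                continue  # neither start nor stop
            if codon in STOP_CODONS and start_at is not None:
                calls.append((strand, frame, start_at, p + 3, True, True))
                start_at = None
            elif codon in STOP_CODONS:
                continue
            elif start_at is None and codon in START_CODONS:
                start_at = p
        if start_at is not None:
            end = start_at + 3 * ((n - start_at) // 3)
            calls.append((strand, frame, start_at, end, True, False))
    out = []
    for strand_, frame, a, b, hs, hp in calls:
        if strand_ == "-":  # map back to forward coordinates
            a, b = n - b, n - a
        out.append(OrfCall(strand=strand_, frame=frame, start=a, end=b,
                           n_codons=(b - a) // 3, has_start=hs, has_stop=hp))
    return out


def scan_orfs(sequence: str, genetic_code: int = 11) -> list[OrfCall]:
    """All maximal ORFs in the 6 frames of *sequence*.

    A maximal ORF runs from the first start codon after the previous in-frame
    stop to the next in-frame stop.  Codons containing N are neither starts
    nor stops.  Sorted by n_codons descending, ties by strand (+ first), then
    leftmost.
    """
    if genetic_code != 11:
        raise ValueError("only the bacterial genetic code (11) is supported")
    seq = sequence.upper().replace("U", "T")
    calls = _scan_strand(seq, "+") + _scan_strand(_revcomp(seq), "-")
    calls.sort(key=lambda o: (-o.n_codons, o.strand != "+", o.start))
    return calls


class ExternalProteinSearch(Protocol):
    """Adapter contract for a real translated-homology search.

    The callable receives FASTA text and returns TSV lines of
    ``(query_id, hit_accession, e_value)``; hits at e <= 1e-5 count.
    """

    def __call__(self, fasta_text: str) -> str: ...


def parse_protein_search_tsv(tsv_text: str, max_evalue: float = 1e-5) -> set[str]:
    """Query ids with at least one hit at e <= *max_evalue*."""
    hits = set()
    for line in tsv_text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            continue
        try:
            e = float(parts[2])
        except ValueError:
            continue
        if e <= max_evalue:
            hits.add(parts[0])
    return hits


def flag_coding(igr: IGR, min_codons: int = 50,
                external_hits: bool | None = None) -> bool:
    """True iff the IGR looks protein-coding; flagged IGRs become known_orf.

    The rule: the longest complete ORF (has_start and has_stop) reaches
    ``min_codons``, or an external protein search reported a hit for this IGR
    (the adapter verdict overrides the ORF heuristic).
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    coding = bool(external_hits)
    if not coding:
        for orf in scan_orfs(igr.sequence):
            if orf.has_start and orf.has_stop and orf.n_codons >= min_codons:
                coding = True
                break
    if coding:
        igr.status = "known_orf"
    return coding
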