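"""Grouping homologous candidate IGRs into motifs.

Homologs are found by k-mer containment similarity (strand-aware) and merged
by single-linkage clustering; each group is strand-normalized and built into
a center-star multiple alignment.  This is a desk-scale substitute for
iterative covariance-model searching: an adapter hook
(:class:`ExternalHomologySearch`) marks where a profile-based search engine
could be plugged in instead.
"""

from __future__ import annotations

from typing import Protocol

from Bio import Align

from .genome_io import IGR, MotifAlignment, MotifRow

__all__ = [
    "dedupe_unique",
    "kmer_similarity",
    "cluster_homologs",
    "align_group",
    "orient_group",
    "build_motif",
    "ExternalHomologySearch",
]

_COMP = str.maketrans("ACGTU", "TGCAA")

DEFAULT_K = 6
DEFAULT_THRESHOLD = 0.35


def _revcomp_dna(s: str) -> str:
    return s.upper().replace("U", "T").translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def dedupe_unique(sequences: list[str]) -> tuple[int, list[int]]:
    """Count distinct sequences after uppercasing and T->U normalization.

    Returns ``(n_unique, representative_indices)`` where each representative
    index is the first occurrence of its sequence.
    """
    seen: dict[str, int] = {}
    reps = []
    for i, s in enumerate(sequences):
        key = s.upper().replace("T", "U")
        if key not in seen:
            seen[key] = i
            reps.append(i)
    return len(seen), reps


def _kmers(s: str, k: int) -> set[str]:
    return {s[i:i + k] for i in range(len(s) - k + 1)}


def kmer_similarity(a: str, b: str, k: int = DEFAULT_K) -> float:
    """Strand-aware k-mer containment in [0, 1].

    ``|kmers(a) & kmers(b)| / min(|kmers(a)|, |kmers(b)|)`` computed for b on
    both strands, returning the max; symmetric by construction.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    if len(a) < k or len(b) < k:
        raise ValueError("sequence shorter than k")
    ka = _kmers(a, k)
    best = 0.0
    for bb in (b, _revcomp_dna(b)):
        kb = _kmers(bb, k)
        best = max(best, len(ka & kb) / min(len(ka), len(kb)))
    return best


class _UnionFind:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, x):
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[max(ra, rb)] = min(ra, rb)


def cluster_homologs(candidates: list[IGR], k: int = DEFAULT_K,
                     threshold: float = DEFAULT_THRESHOLD) -> list[list[IGR]]:
    """Single-linkage clusters over the similarity graph.

    An edge joins two candidates when their k-mer containment reaches
    ``threshold``.  Groups are ordered (and internally ordered) by
    lexicographically smallest member igr_id, which makes the result
    invariant to input order.  Singletons are allowed.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    igrs = sorted(candidates, key=lambda g: g.igr_id)
    n = len(igrs)
    kmer_f = [_kmers(g.sequence.upper().replace("U", "T"), k) for g in igrs]
    kmer_r = [_kmers(_revcomp_dna(g.sequence), k) for g in igrs]
    uf = _UnionFind(n)
    for i in range(n):
        ki = kmer_f[i]
        for j in range(i + 1, n):
            if uf.find(i) == uf.find(j):
                continue
            denom_f = min(len(ki), len(kmer_f[j]))
            sim = max(len(ki & kmer_f[j]), len(ki & kmer_r[j])) / denom_f
            if sim >= threshold:
                uf.union(i, j)
    groups: dict[int, list[IGR]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(igrs[i])
    return [groups[r] for r in sorted(groups, key=lambda r: igrs[r].igr_id)]


def orient_group(members: list[IGR], k: int = DEFAULT_K,
                 max_utr_gap: int = 100) -> tuple[list[str], list[str], int]:
    """Strand-normalize a group to its seed and the downstream-gene convention.

    The seed is the member with the highest total similarity to the rest
    (ties: smallest igr_id).  Every member is flipped, when needed, to the
    orientation that best matches the seed.  If flipping the whole group
    would put a clear majority of members (>= 75%) immediately upstream of a
    same-strand gene within ``max_utr_gap`` nt — the 5'-UTR convention —
    while the seed orientation does not, the group is flipped; chance
    near-50% splits never flip a group away from its seed orientation.

    Returns ``(sequences, strands, seed_index)`` with sequences in the
    normalized orientation.
    """
    n = len(members)
    if n == 1:
        seq = members[0].sequence.upper().replace("U", "T")
        if (_downstream_count(members, ["-"], max_utr_gap) == 1
                and _downstream_count(members, ["+"], max_utr_gap) == 0):
            return [_revcomp_dna(seq)], ["-"], 0
        return [seq], ["+"], 0
    raw = [m.sequence.upper().replace("U", "T") for m in members]
    sims = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            s = kmer_similarity(raw[i], raw[j], k)
            sims[i][j] = sims[j][i] = s
    totals = [sum(row) for row in sims]
    seed = min(range(n), key=lambda i: (-totals[i], members[i].igr_id))
    seqs, strands = [], []
    kf = _kmers(raw[seed], k)
    for i in range(n):
        fwd = len(kf & _kmers(raw[i], k))
        rev = len(kf & _kmers(_revcomp_dna(raw[i]), k))
        if rev > fwd:
            seqs.append(_revcomp_dna(raw[i]))
            strands.append("-")
        else:
            seqs.append(raw[i])
            strands.append("+")
    flipped = ["-" if s == "+" else "+" for s in strands]
    n_cur = _downstream_count(members, strands, max_utr_gap)
    n_flip = _downstream_count(members, flipped, max_utr_gap)
    if n_flip >= 0.75 * n and n_flip > n_cur and n_cur < 0.75 * n:
        seqs = [_revcomp_dna(s) for s in seqs]
        strands = flipped
    return seqs, strands, seed


def _downstream_count(members, strands, max_utr_gap):
    """How many members have a same-strand gene just downstream, given strands."""
    count = 0
    for m, strand in zip(members, strands):
        if strand == "+":
            g = m.right_gene
            if g is not None and g.strand == "+" and 0 <= g.start - m.end <= max_utr_gap:
                count += 1
        else:
            g = m.left_gene
            if g is not None and g.strand == "-" and 0 <= m.start - g.end <= max_utr_gap:
                count += 1
    return count


def make_aligner() -> Align.PairwiseAligner:
    """Global pairwise aligner: match +2, mismatch -1, gap open -4, extend -1.

    A gap of length L costs 4 + (L - 1).
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def pairwise_align(a: str, b: str):
    """(gapped_a, gapped_b, score) of the optimal global alignment."""
    aligner = make_aligner()
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


def align_group(seqs: list[str], seed_index: int = 0) -> list[str]:
    """Center-star multiple alignment around ``seqs[seed_index]``.

    Every member is globally aligned to the seed; the pairwise gap patterns
    are merged by taking, between consecutive seed positions, the maximum
    insertion length observed in any pairwise alignment.  The result is
    rectangular and deterministic.
    """
    if not seqs:
        raise ValueError("empty group")
    if len(seqs) == 1:
        return [seqs[0]]
    seed = seqs[seed_index]
    pairwise = []
    for i, s in enumerate(seqs):
        if i == seed_index:
            pairwise.append((seed, seed))
        else:
            ga, gb, _ = pairwise_align(seed, s)
            pairwise.append((ga, gb))
    m = len(seed)
    # ins[p] = longest insertion before seed position p (p == m: after end)
    ins = [0] * (m + 1)
    parsed = []
    for ga, gb in pairwise:
        segs: dict[int, str] = {}
        cols: list[tuple[int, str]] = []  # (seed_pos or -1 for insertion, member char)
        p = 0
        run = 0
        for ca, cb in zip(ga, gb):
            if ca == "-":
                run += 1
                cols.append((-1, cb))
            else:
                if run:
                    ins[p] = max(ins[p], run)
                    run = 0
                cols.append((p, cb))
                p += 1
        if run:
            ins[m] = max(ins[m], run)
        parsed.append(cols)
    out = []
    for cols in parsed:
        row = []
        pending: list[str] = []
        p = 0
        for pos, cb in cols:
            if pos == -1:
                pending.append(cb)
            else:
                row.append("".join(pending).rjust(ins[p], "-"))
                pending = []
                row.append(cb)
                p += 1
        row.append("".join(pending).rjust(ins[m], "-"))
        out.append("".join(row))
    width = m + sum(ins)
    assert all(len(r) == width for r in out)
    return out


def build_motif(motif_id: str, members: list[IGR], k: int = DEFAULT_K,
                max_utr_gap: int = 100) -> MotifAlignment:
    """Orient, align and package one cluster as a MotifAlignment.

    Row sequences are shown in the RNA alphabet (T -> U); gap columns use
    '-'.  Row coordinates are the member IGR's genomic interval with the
    normalized strand.
    """
    seqs, strands, seed = orient_group(members, k=k, max_utr_gap=max_utr_gap)
    aligned = align_group(seqs, seed_index=seed)
    rows = [
        MotifRow(igr_id=m.igr_id, genome_id=m.genome_id, start=m.start,
                 end=m.end, strand=strand, seq=g.replace("T", "U"))
        for m, strand, g in zip(members, strands, aligned)
    ]
    return MotifAlignment(motif_id=motif_id, rows=rows)


def flip_motif(motif: MotifAlignment) -> MotifAlignment:
    """Reverse-complement a whole motif alignment in place.

    Rows are reverse-complemented (gap columns mirrored), strands swapped,
    and ``ss_cons`` mirrored with brackets exchanged.  Pair canonicity is
    preserved under reverse complement, so the mirrored structure scores
    identically; per-column stats must be recomputed by the caller.
    """
    swap = str.maketrans("<>()[]{}", "><)(][}{")
    for row in motif.rows:
        comp = row.seq.upper().translate(str.maketrans("ACGUT", "UGCAA"))[::-1]
        row.seq = comp
        row.strand = "-" if row.strand == "+" else "+"
    if motif.ss_cons is not None:
        motif.ss_cons = motif.ss_cons.translate(swap)[::-1]
    motif.column_stats = None
    return motif


class ExternalHomologySearch(Protocol):
    """Hook for a covariance-model search engine.

    Receives a Stockholm alignment as text plus a FASTA database and returns
    additional homologous hits as ``(sequence_id, start, end, strand)``
    tuples; results can be merged into the candidate pool and re-clustered.
    """

    def __call__(self, stockholm_text: str, fasta_db: str) -> list[tuple]: ...
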