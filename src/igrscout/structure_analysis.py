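"""Consensus structure and regulatory-feature analysis of motif alignments.

Per-column conservation classes, base-pair covariation evidence, a
covariation-weighted base-pair-maximization consensus fold, and detectors for
the regulatory features the classifier consumes: intrinsic terminators
(hairpin + poly-U tail), Shine-Dalgarno proximity/sequestration, and
conserved upstream ORFs.

Covariation is the evidence standard throughout: paired columns where
substitutions on one side are matched by compensatory changes on the other,
preserving canonical (Watson-Crick or G·U) pairing.  Columns pairs are graded
``covarying`` (>= 2 canonical pair types at >= 97% canonical rows),
``compatible`` (>= 75% canonical) or ``unsupported``; the consensus fold only
pairs supported columns, weighting covarying ones heavily.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import IGR, GeneFeature, MotifAlignment, ss_pairs

__all__ = [
    "ConservationClass", "PairEvidence", "TerminatorCall", "SDCall", "UorfCall",
    "conservation_profile", "pair_covariation", "pair_class_matrix",
    "fold_consensus", "consensus_sequence", "count_stems", "hairpins_of",
    "find_terminator", "find_sd", "find_uorf", "pseudoknot_note",
]

CANONICAL = {"AU", "UA", "GC", "CG", "GU", "UG"}

COVARY_CANONICAL_FRAC = 0.97
COMPATIBLE_CANONICAL_FRAC = 0.75
MIN_PAIR_ROWS = 3

_GAP = {"-", ".", "_", "~"}


def _norm_char(c: str) -> str:
    c = c.upper()
    if c == "T":
        return "U"
    return c


@dataclass(frozen=True)
class ConservationClass:
    """Conservation grade of one alignment column (R2R-style thresholds)."""

    column: int
    dominant_nt: str | None
    level: str  # n97 | n90 | n75 | present | variable
    gap_fraction: float


def conservation_profile(aln: MotifAlignment) -> list[ConservationClass]:
    """Dominant nucleotide and conservation level per column.

    Levels use non-gap rows only: n97 / n90 / n75 when the dominant
    nucleotide reaches 97 / 90 / 75%, ``present`` when a nucleotide still
    dominates half the rows, else ``variable``.  Columns that are gaps in
    more than half the rows are ``variable`` outright.
    """
    if aln.width == 0:
        raise ValueError("width-0 alignment")
    out = []
    nrows = len(aln.rows)
    for c in range(aln.width):
        col = [_norm_char(r.seq[c]) for r in aln.rows]
        nongap = [x for x in col if x not in _GAP]
        gap_fraction = 1 - len(nongap) / nrows
        if not nongap or gap_fraction > 0.5:
            out.append(ConservationClass(c, None, "variable", gap_fraction))
            continue
        counts = {}
        for x in nongap:
            counts[x] = counts.get(x, 0) + 1
        dom, nd = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        f = nd / len(nongap)
        if f >= 0.97:
            level = "n97"
        elif f >= 0.90:
            level = "n90"
        elif f >= 0.75:
            level = "n75"
        elif f >= 0.50:
            level = "present"
        else:
            level = "variable"
        out.append(ConservationClass(c, dom if level != "variable" else None,
                                     level, gap_fraction))
    return out


@dataclass(frozen=True)
class PairEvidence:
    """Covariation evidence for one column pair (i < j)."""

    i: int
    j: int
    n_canonical: int
    n_noncanonical: int
    n_pair_types: int
    klass: str  # covarying | compatible | unsupported


def pair_covariation(aln: MotifAlignment, i: int, j: int) -> PairEvidence:
    """Grade columns (i, j) on rows non-gap at both positions.

    covarying: >= 2 distinct canonical pair types and canonical fraction
    >= 0.97; compatible: canonical fraction >= 0.75; otherwise unsupported.
    Fewer than 3 usable rows is always unsupported.
    """
    if not i < j:
        raise ValueError("need i < j")
    pairs = []
    for r in aln.rows:
        a, b = _norm_char(r.seq[i]), _norm_char(r.seq[j])
        if a in _GAP or b in _GAP:
            continue
        pairs.append(a + b)
    n_can = sum(1 for p in pairs if p in CANONICAL)
    n_non = len(pairs) - n_can
    types = len({p for p in pairs if p in CANONICAL})
    if len(pairs) < MIN_PAIR_ROWS:
        klass = "unsupported"
    else:
        frac = n_can / len(pairs)
        if types >= 2 and frac >= COVARY_CANONICAL_FRAC:
            klass = "covarying"
        elif frac >= COMPATIBLE_CANONICAL_FRAC:
            klass = "compatible"
        else:
            klass = "unsupported"
    return PairEvidence(i, j, n_can, n_non, types, klass)


_NT_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_CANON_CODES = np.zeros(16, dtype=bool)
for _p in CANONICAL:
    _CANON_CODES[_NT_CODE[_p[0]] * 4 + _NT_CODE[_p[1]]] = True


def _encode(aln: MotifAlignment) -> np.ndarray:
    X = np.full((len(aln.rows), aln.width), 4, dtype=np.int8)
    for r, row in enumerate(aln.rows):
        for c, ch in enumerate(row.seq):
            X[r, c] = _NT_CODE.get(_norm_char(ch), 4)
    return X


def pair_class_matrix(aln: MotifAlignment) -> np.ndarray:
    """Class of every column pair: 0 unsupported, 1 compatible, 2 covarying.

    Vectorized equivalent of :func:`pair_covariation` over all i < j,
    symmetric.
    """
    X = _encode(aln)
    W = aln.width
    out = np.zeros((W, W), dtype=np.int8)
    valid_nt = X < 4
    for i in range(W):
        left = X[:, i]
        ok = valid_nt[:, i][:, None] & valid_nt  # rows valid at i and every j
        code = (left[:, None] * 4 + X).clip(0, 15)
        canon = _CANON_CODES[code] & ok
        n_valid = ok.sum(axis=0)
        n_canon = canon.sum(axis=0)
        types = np.zeros(W, dtype=np.int8)
        for c in np.flatnonzero(_CANON_CODES):
            types += ((code == c) & ok).any(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(n_valid > 0, n_canon / np.maximum(n_valid, 1), 0.0)
        enough = n_valid >= MIN_PAIR_ROWS
        cov = enough & (types >= 2) & (frac >= COVARY_CANONICAL_FRAC)
        comp = enough & ~cov & (frac >= COMPATIBLE_CANONICAL_FRAC)
        out[i, cov] = 2
        out[i, comp] = 1
    out[np.arange(W), np.arange(W)] = 0
    return out


def fold_consensus(aln: MotifAlignment, min_loop: int = 3,
                   bonus_covary: float = 3.0,
                   bonus_compatible: float = 1.0) -> str:
    """Covariation-weighted base-pair-maximization consensus structure.

    Nussinov-style dynamic program over alignment columns: a pair (i, j)
    scores ``bonus_covary`` when covarying, ``bonus_compatible`` when
    compatible, and is forbidden when unsupported; every pair must span more
    than ``min_loop`` columns, which keeps hairpin loops at least that long.
    Columns that are gaps in more than half the rows (insertion columns)
    never pair — a handful of inserted rows is not evidence for a consensus
    helix.
    Traceback is deterministic: pairing the interval ends is preferred on
    ties, then leaving the right end unpaired, then the smallest split point.
    Returns a balanced angle-bracket string of the alignment width.
    """
    aln.validate()
    W = aln.width
    if W < min_loop + 2:
        return "." * W
    if len(aln.rows) < MIN_PAIR_ROWS:
        return "." * W
    klass = pair_class_matrix(aln)
    X = _encode(aln)
    gappy = (X == 4).mean(axis=0) > 0.5
    S = np.full((W, W), -np.inf)
    S[klass == 1] = bonus_compatible
    S[klass == 2] = bonus_covary
    S[gappy, :] = -np.inf
    S[:, gappy] = -np.inf

    P = np.zeros((W, W))
    for span in range(min_loop + 1, W):
        for i in range(W - span):
            j = i + span
            best = P[i, j - 1]
            ks = np.arange(i, j - min_loop)
            left = np.where(ks > i, P[i, np.maximum(ks - 1, 0)], 0.0)
            cand = left + S[ks, j] + P[ks + 1, j - 1]
            if cand.size:
                best = max(best, float(cand.max()))
            P[i, j] = best

    ss = ["."] * W
    stack = [(0, W - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        target = P[i, j]
        if target <= 0:
            continue
        inner = P[i + 1, j - 1] if i + 1 <= j - 1 else 0.0
        if np.isfinite(S[i, j]) and np.isclose(S[i, j] + inner, target):
            ss[i], ss[j] = "<", ">"
            stack.append((i + 1, j - 1))
            continue
        if np.isclose(P[i, j - 1], target):
            stack.append((i, j - 1))
            continue
        for k in range(i + 1, j - min_loop):
            left = P[i, k - 1]
            right = P[k + 1, j - 1] if k + 1 <= j - 1 else 0.0
            if np.isfinite(S[k, j]) and np.isclose(left + S[k, j] + right, target):
                ss[k], ss[j] = "<", ">"
                stack.append((i, k - 1))
                stack.append((k + 1, j - 1))
                break
        else:  # numerical fallback: treat j as unpaired
            stack.append((i, j - 1))
    return "".join(ss)


def consensus_sequence(aln: MotifAlignment) -> str:
    """Dominant nucleotide per column ('N' where variable), RNA alphabet."""
    return "".join((cc.dominant_nt or "N") for cc in conservation_profile(aln))


def helix_runs(pairs, max_bulge: int = 2) -> list[list[tuple[int, int]]]:
    """Group base pairs into helices, tolerating small interruptions.

    Consecutive pairs belong to one helix when the unpaired gap between them
    totals at most *max_bulge* nucleotides over both strands — the usual
    reading in which a stem interrupted by a 1-2 nt bulge is still one stem.
    """
    runs: list[list[tuple[int, int]]] = []
    for i, j in sorted(pairs):
        if runs:
            a, b = runs[-1][-1]
            da, db = i - a, b - j
            if 1 <= da <= max_bulge + 1 and 1 <= db <= max_bulge + 1 \
                    and (da - 1) + (db - 1) <= max_bulge:
                runs[-1].append((i, j))
                continue
        runs.append([(i, j)])
    return runs


def count_stems(ss: str, min_bp: int = 3) -> int:
    """Number of helices with at least *min_bp* pairs (small bulges allowed)."""
    return sum(1 for run in helix_runs(ss_pairs(ss)) if len(run) >= min_bp)


def hairpins_of(ss: str) -> list[dict]:
    """Hairpins in a structure string: the helix closing each terminal loop.

    A helix is hairpin-forming when no pair lies inside its innermost pair.
    Returns dicts with keys stem5 (start of 5' arm), stem3 (end of 3' arm,
    inclusive), stem_bp (pairs in the helix), loop_len, ordered 5' to 3' by
    stem3.
    """
    pairs = sorted(ss_pairs(ss))
    out = []
    for run in helix_runs(pairs):
        ai, bi = run[-1]  # innermost pair of the helix
        if any(ai < p[0] and p[1] < bi for p in pairs):
            continue  # encloses other helices: not a hairpin
        out.append(dict(stem5=run[0][0], stem3=run[0][1], stem_bp=len(run),
                        loop_len=bi - ai - 1))
    out.sort(key=lambda h: h["stem3"])
    return out


@dataclass(frozen=True)
class TerminatorCall:
    """Decision on an intrinsic-terminator hairpin (stem + >= 5-U tail)."""

    stem5: int = -1
    stem3: int = -1
    stem_bp: int = 0
    loop_len: int = 0
    u_run: int = 0
    is_terminator: bool = False


_U_WINDOW = 8
_MIN_U_RUN = 5
_LOOP_RANGE = (3, 10)
_PAIR_OK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def _u_run(tail: str) -> int:
    """U count in the first 8 tail positions; 0 unless the tail starts UU."""
    w = tail[:_U_WINDOW]
    if len(w) < 2 or w[0] != "U" or w[1] != "U":
        return 0
    return w.count("U")


def find_terminator(consensus_seq: str, fold: str | None = None,
                    min_stem: int = 6) -> TerminatorCall:
    """Intrinsic-terminator detection.

    With *fold*, examines the 3'-most hairpin of the given consensus
    structure; the call is positive when that hairpin has >= ``min_stem``
    stacked pairs, a loop of 3-10 nt, and a run of >= 5 U among the 8
    positions after the stem's 3' end (the first two of which must be U).

    Without *fold*, scans the sequence itself: anchors at every qualifying
    U-tail and grows a complementary stem (canonical incl. G·U) behind it
    over loop sizes 3-10; the 3'-most qualifying hairpin is reported.
    """
    s = consensus_seq.upper().replace("T", "U")
    if fold is not None:
        if len(s) != len(fold):
            raise ValueError("consensus and fold lengths differ")
        hps = hairpins_of(fold)
        if not hps:
            return TerminatorCall()
        h = hps[-1]  # 3'-most
        u = _u_run(s[h["stem3"] + 1:])
        ok = (h["stem_bp"] >= min_stem
              and _LOOP_RANGE[0] <= h["loop_len"] <= _LOOP_RANGE[1]
              and u >= _MIN_U_RUN)
        return TerminatorCall(h["stem5"], h["stem3"], h["stem_bp"],
                              h["loop_len"], u, ok)
    # sequence-only scan, 3'-most tail first
    n = len(s)
    for t in range(n - 2, -1, -1):  # t = first tail position (after stem 3' end)
        u = _u_run(s[t:])
        if u < _MIN_U_RUN:
            continue
        for loop in range(_LOOP_RANGE[0], _LOOP_RANGE[1] + 1):
            max_m = (t - loop) // 2
            for m in range(min_stem, max_m + 1):
                a = t - 2 * m - loop  # start of the 5' arm
                if a < 0:
                    break
                if all((s[a + x], s[t - 1 - x]) in _PAIR_OK for x in range(m)):
                    return TerminatorCall(stem5=a, stem3=t - 1, stem_bp=m,
                                          loop_len=loop, u_run=u,
                                          is_terminator=True)
    return TerminatorCall()


@dataclass(frozen=True)
class SDCall:
    """A putative Shine-Dalgarno match upstream of a start codon."""

    position: tuple[int, int]  # interval in the upstream window, 0 = start codon
    core_len: int
    spacing_to_start: int
    overlaps_structure: bool = False


_ANTI_SD = "AGGAGG"
_SD_WINDOW = (4, 15)  # nt upstream of the start codon


def find_sd(igr: IGR, downstream_gene: GeneFeature, genome_seq: str | None = None,
            paired_positions: set[int] | None = None) -> SDCall | None:
    """Scan 4-15 nt upstream of the gene's start codon for an SD core.

    The core is the longest contiguous substring of AGGAGG (>= 4 nt) lying
    inside the window; ``spacing_to_start`` is the gap between the core's 3'
    end and the start codon.  ``paired_positions`` (genome coordinates of
    columns paired in the consensus structure) sets ``overlaps_structure``.
    Returns None when no core is found.
    """
    seq = genome_seq if genome_seq is not None else None
    win = _SD_WINDOW[1] + len(_ANTI_SD)
    if downstream_gene.strand == "+":
        gstart = downstream_gene.start
        lo = max(gstart - win, 0)
        if seq is None:
            if not (igr.start <= lo and gstart <= igr.end):
                return None
            upstream = igr.sequence[lo - igr.start:gstart - igr.start]
        else:
            upstream = seq[lo:gstart]
        def genome_pos(up_off):  # offset within upstream -> genome coordinate
            return lo + up_off
    else:
        gstart = downstream_gene.end  # start codon at the right edge
        hi = gstart + win
        if seq is None:
            if not (igr.start <= gstart and hi <= igr.end):
                return None
            region = igr.sequence[gstart - igr.start:hi - igr.start]
        else:
            region = seq[gstart:hi]
        upstream = _rc(region)
        def genome_pos(up_off):
            return gstart + (len(upstream) - 1 - up_off)

    upstream = upstream.upper().replace("T", "U")
    anti = _ANTI_SD  # no T/U letters, identical in DNA and RNA alphabets
    L = len(upstream)
    best = None
    for c in range(len(anti), 3, -1):  # longest core first
        cores = {anti[k:k + c] for k in range(len(anti) - c + 1)}
        for d in range(_SD_WINDOW[0], _SD_WINDOW[1] - c + 1):  # spacing, small first
            start = L - d - c
            if start < 0:
                continue
            if upstream[start:start + c] in cores:
                best = (c, d, start)
                break
        if best:
            break
    if not best:
        return None
    c, d, start = best
    overlaps = False
    if paired_positions:
        gp = {genome_pos(o) for o in range(start, start + c)}
        overlaps = bool(gp & paired_positions)
    return SDCall(position=(start, start + c), core_len=c,
                  spacing_to_start=d, overlaps_structure=overlaps)


def _rc(s: str) -> str:
    return s.upper().replace("U", "T").translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass(frozen=True)
class UorfCall:
    """A conserved upstream ORF detected across alignment rows."""

    start_column: int
    stop_column: int
    frame_consistent_fraction: float
    conserved: bool


_STOPS_RNA = {"UAA", "UAG", "UGA"}


def find_uorf(aln: MotifAlignment, min_rows_fraction: float = 0.8) -> UorfCall | None:
    """Earliest alignment column where a conserved start codon opens an ORF.

    A column qualifies when >= ``min_rows_fraction`` of rows read AUG at
    their ungapped position under that column, and >= the same fraction of
    those rows reach an in-frame stop codon before the row's end.  Fewer
    than 3 rows cannot support a conservation claim (the same evidential
    floor as pair covariation) and returns None.
    """
    aln.validate()
    nrows = len(aln.rows)
    if nrows < MIN_PAIR_ROWS:
        return None
    ungapped = []
    col_of: list[list[int]] = []  # per row: ungapped index -> column
    pos_at: list[list[int | None]] = []  # per row: column -> ungapped index
    for r in aln.rows:
        u = []
        cols = []
        pos = []
        for c, ch in enumerate(r.seq):
            ch = _norm_char(ch)
            if ch in _GAP:
                pos.append(None)
            else:
                pos.append(len(u))
                u.append(ch)
                cols.append(c)
        ungapped.append("".join(u))
        col_of.append(cols)
        pos_at.append(pos)
    for c in range(aln.width - 2):
        aug_rows = []
        for ri in range(nrows):
            p = pos_at[ri][c]
            if p is None:
                continue
            if ungapped[ri][p:p + 3] == "AUG":
                aug_rows.append((ri, p))
        if len(aug_rows) / nrows < min_rows_fraction:
            continue
        stop_cols = []
        for ri, p in aug_rows:
            q = p + 3
            u = ungapped[ri]
            while q + 3 <= len(u):
                if u[q:q + 3] in _STOPS_RNA:
                    stop_cols.append(col_of[ri][q])
                    break
                q += 3
        frac = len(stop_cols) / len(aug_rows)
        if frac >= min_rows_fraction:
            # majority stop column
            counts = {}
            for sc in stop_cols:
                counts[sc] = counts.get(sc, 0) + 1
            stop_col = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]
            return UorfCall(start_column=c, stop_column=stop_col,
                            frame_consistent_fraction=frac, conserved=True)
    return None


def pseudoknot_note(aln: MotifAlignment, fold: str, min_len: int = 4) -> bool:
    """Flag when two hairpin loops are reverse-complementary over >= min_len nt.

    Reported as a note only — pseudoknots are never folded.
    """
    cons = consensus_sequence(aln)
    loops = []
    for h in hairpins_of(fold):
        a = h["stem5"] + h["stem_bp"]
        b = h["stem3"] - h["stem_bp"] + 1
        loops.append(cons[a:b])
    for x in range(len(loops)):
        for y in range(x + 1, len(loops)):
            la, lb = loops[x], _rc(loops[y]).replace("T", "U")
            for i in range(len(la) - min_len + 1):
                if la[i:i + min_len] != "N" * min_len and la[i:i + min_len] in lb:
                    return True
    return False
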