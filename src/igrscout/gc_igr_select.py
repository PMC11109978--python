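"""%GC / length selection of candidate intergenic regions.

In AT-rich bacterial genomes, IGRs that template structured ncRNAs are on
average longer and GC-richer than the rest, so they concentrate in the upper
right quadrant of a (%GC, length) scatter.  The selection region is an
axis-aligned quadrant ``{pct_gc >= gc_min and length_nt >= len_min}`` fitted
so that it (a) covers at least a target fraction of the IGRs known to carry
annotated ncRNAs and (b) among such corners admits a number of unknown IGRs
as close as possible to the number of known ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import IGR, pct_gc  # noqa: F401  (pct_gc re-exported here)

__all__ = ["SelectionRegion", "pct_gc", "fit_selection_region",
           "select_candidates", "export_scatter"]


@dataclass
class SelectionRegion:
    """The fitted upper-right quadrant and its bookkeeping."""

    gc_min: float
    len_min: int
    n_known_inside: int
    n_unknown_inside: int
    coverage_achieved: float

    def contains(self, gc: float, length: int) -> bool:
        return gc >= self.gc_min and length >= self.len_min


def fit_selection_region(known_pts, unknown_pts, coverage: float = 0.9,
                         balance_tol: float = 0.1) -> SelectionRegion:
    """Fit the quadrant corner over the grid of known-point coordinates.

    Candidate corners are every (gc, length) combination drawn from the
    observed known-point coordinates plus (0, 0).  A corner is feasible when
    at least ``coverage`` of the known points fall inside; among feasible
    corners the one minimizing ``|n_unknown_inside - n_known_inside|`` wins,
    ties broken by larger gc_min, then larger len_min.  ``balance_tol`` is
    informational only (the achieved balance is reported, not enforced).
    """
    if not len(known_pts):
        raise ValueError("known_pts must be nonempty")
    if not (0 < coverage <= 1):
        raise ValueError("coverage must be in (0, 1]")
    kn = np.asarray(known_pts, dtype=float).reshape(-1, 2)
    un = (np.asarray(unknown_pts, dtype=float).reshape(-1, 2)
          if len(unknown_pts) else np.empty((0, 2)))
    gcs = np.unique(np.concatenate([[0.0], kn[:, 0]]))
    lens = np.unique(np.concatenate([[0.0], kn[:, 1]]))

    # counts[g, l] = #points with gc >= gcs[g] and len >= lens[l]
    def _counts(pts):
        if not len(pts):
            return np.zeros((len(gcs), len(lens)), dtype=int)
        gmask = pts[:, 0][:, None] >= gcs[None, :]   # (n, nG)
        lmask = pts[:, 1][:, None] >= lens[None, :]  # (n, nL)
        return gmask.T.astype(np.int64) @ lmask.astype(np.int64)

    k_in = _counts(kn)
    u_in = _counts(un)
    feasible = k_in >= coverage * len(kn) - 1e-9
    if not feasible.any():  # unreachable: (0,0) contains everything
        raise RuntimeError("no feasible corner")
    diff = np.abs(u_in - k_in)
    best = None
    gi_idx, li_idx = np.nonzero(feasible)
    for gi, li in zip(gi_idx, li_idx):
        key = (diff[gi, li], -gcs[gi], -lens[li])
        if best is None or key < best[0]:
            best = (key, gi, li)
    _, gi, li = best
    return SelectionRegion(
        gc_min=float(gcs[gi]), len_min=int(lens[li]),
        n_known_inside=int(k_in[gi, li]), n_unknown_inside=int(u_in[gi, li]),
        coverage_achieved=float(k_in[gi, li] / len(kn)),
    )


def select_candidates(igrs: list[IGR], region: SelectionRegion) -> list[IGR]:
    """Unknown-status IGRs inside the region, promoted to status=candidate.

    Known-RNA IGRs are never returned (they are counted by the fit, then
    removed from the analysis), nor are IGRs already flagged as coding.
    """
    out = []
    for igr in igrs:
        if igr.status != "unknown":
            continue
        if region.contains(igr.pct_gc, igr.length_nt):
            igr.status = "candidate"
            out.append(igr)
    return out


def export_scatter(igrs: list[IGR], region: SelectionRegion | None, path,
                   fig_path=None) -> None:
    """TSV of (igr_id, pct_gc, length_nt, status), ordered by igr_id.

    With *fig_path*, also draws the scatter with the region's two threshold
    lines.
    """
    rows = sorted(igrs, key=lambda g: g.igr_id)
    with open(path, "w") as fh:
        fh.write("igr_id\tpct_gc\tlength_nt\tstatus\n")
        for g in rows:
            fh.write(f"{g.igr_id}\t{g.pct_gc:.3f}\t{g.length_nt}\t{g.status}\n")
    if fig_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 5))
        palette = {"unknown": "0.7", "candidate": "tab:blue",
                   "known_rna": "tab:green", "known_orf": "tab:orange"}
        for status, color in palette.items():
            pts = [(g.pct_gc, g.length_nt) for g in rows if g.status == status]
            if pts:
                xs, ys = zip(*pts)
                ax.scatter(xs, ys, s=8, c=color, label=status, alpha=0.6)
        if region is not None:
            ax.axvline(region.gc_min, ls="--", c="k", lw=0.8)
            ax.axhline(region.len_min, ls="--", c="k", lw=0.8)
        ax.set_xlabel("%GC")
        ax.set_ylabel("IGR length (nt)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
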