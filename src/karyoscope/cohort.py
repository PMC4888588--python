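"""Population-level utilities: pseudo-bulk aggregation, cell clustering,
genome-wide heatmaps and near-tetraploid odd-state detection.

Pseudo-bulk sums the single-cell libraries into one track, emulating a bulk
measurement; minority subclones average away in that view while remaining
visible to the single-cell heterogeneity score — the central contrast
between bulk and single-cell karyotyping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .counts import CellCounts
from .genome import BinGrid
from .hmm import CopyNumberProfile


@dataclass
class PseudoBulkTrack:
    """Summed counts across cells plus a ploidy-scaled coverage track.

    ``normalised`` is counts per Mb rescaled so the population median
    equals the baseline ploidy, i.e. a euploid region reads ~2 in a
    diploid-baseline genome; ``rounded_states`` rounds that to integers.
    """

    grid: BinGrid
    summed: np.ndarray
    normalised: np.ndarray

    @property
    def rounded_states(self) -> np.ndarray:
        return np.rint(self.normalised).astype(np.int64)

    def to_bedgraph(self, path) -> None:
        pd.DataFrame({
            "chrom": self.grid.chroms, "start": self.grid.starts,
            "end": self.grid.ends, "value": self.normalised,
        }).to_csv(path, sep="\t", header=False, index=False)


def _check_shared_grid(grids: list[BinGrid]) -> BinGrid:
    g0 = grids[0]
    for g in grids[1:]:
        if g is g0:
            continue
        if (len(g) != len(g0) or not np.array_equal(g.starts, g0.starts)
                or not np.array_equal(g.chroms, g0.chroms)):
            raise ValueError("cells do not share one bin grid")
    return g0


def pseudobulk(cells: list[CellCounts]) -> PseudoBulkTrack:
    """Exact per-bin summation of raw counts across cells.

    The normalised track is scaled so its median equals the genome's median
    baseline ploidy.
    """
    if not cells:
        raise ValueError("need at least one cell")
    grid = _check_shared_grid([c.grid for c in cells])
    summed = np.sum([c.raw for c in cells], axis=0).astype(np.int64)
    per_mb = summed / (grid.widths / 1e6)
    baseline = grid.baseline_ploidy()
    med = np.median(per_mb[per_mb > 0]) if np.any(per_mb > 0) else 1.0
    normalised = per_mb / med * float(np.median(baseline))
    return PseudoBulkTrack(grid, summed, normalised)


def profile_distance_matrix(profiles: list[CopyNumberProfile]) -> np.ndarray:
    """Pairwise width-weighted mean absolute state difference."""
    grid = _check_shared_grid([p.grid for p in profiles])
    S = np.vstack([p.states for p in profiles]).astype(float)
    w = grid.widths.astype(float)
    w = w / w.sum()
    n = len(profiles)
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(S[i + 1:] - S[i])
        D[i, i + 1:] = diff @ w
    return D + D.T


def cluster_cells(profiles: list[CopyNumberProfile]):
    """Hierarchically cluster cells by copy-number profile similarity.

    Average linkage on the width-weighted mean absolute state difference.
    Returns (leaf order for heatmap plotting, linkage matrix, distance
    matrix).
    """
    if len(profiles) < 2:
        return np.arange(len(profiles)), None, np.zeros((len(profiles),) * 2)
    D = profile_distance_matrix(profiles)
    Z = linkage(squareform(D, checks=False), method="average")
    order = np.asarray(leaves_list(Z))
    return order, Z, D


def modal_chromosome_states(profile: CopyNumberProfile) -> dict[str, int]:
    """Width-weighted majority state per chromosome; ties prefer even states
    (conservative for G2-vs-tetraploid discrimination), then the lower one."""
    out: dict[str, int] = {}
    for chrom, sl in profile.grid.chrom_slices().items():
        states = profile.states[sl]
        w = profile.grid.widths[sl].astype(float)
        weight = np.zeros(int(states.max()) + 1)
        np.add.at(weight, states, w)
        best = np.flatnonzero(weight == weight.max())
        even = best[best % 2 == 0]
        out[chrom] = int(even.min() if len(even) else best.min())
    return out


def odd_state_cells(profiles: list[CopyNumberProfile]) -> list[str]:
    """Cells with at least one chromosome at an odd modal copy number.

    In a sorted 4n population, G2 cells must have even chromosome copies;
    odd modal states therefore flag genuine near-tetraploid cells.
    """
    flagged = []
    for p in profiles:
        if any(s % 2 == 1 for s in modal_chromosome_states(p).values()):
            flagged.append(p.cell_id)
    return flagged


STATE_COLOURS = [
    "#3b4cc0", "#7b9ff9", "#c0c0c0", "#f4987a", "#d6604d", "#b2182b",
    "#8c0d25", "#67001f", "#49001a", "#2d0010", "#16000a",
]


def genomewide_heatmap(profiles: list[CopyNumberProfile], ordering=None,
                       path=None, c_max: int = 10):
    """Cells (rows, in cluster order) x bins (columns) heatmap of states.

    Returns the matplotlib figure; writes ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    grid = _check_shared_grid([p.grid for p in profiles])
    if ordering is None:
        ordering, _, _ = cluster_cells(profiles) if len(profiles) > 1 else (
            np.arange(len(profiles)), None, None)
    M = np.vstack([profiles[i].states for i in np.asarray(ordering)])
    cmap = ListedColormap(STATE_COLOURS[:c_max + 1])
    norm = BoundaryNorm(np.arange(-0.5, c_max + 1), cmap.N)
    fig, ax = plt.subplots(figsize=(12, max(2, 0.18 * len(profiles) + 1)))
    im = ax.imshow(M, aspect="auto", interpolation="nearest", cmap=cmap, norm=norm)
    for sl in list(grid.chrom_slices().values())[:-1]:
        ax.axvline(sl.stop - 0.5, color="white", lw=0.6)
    ax.set_yticks(range(len(profiles)))
    ax.set_yticklabels([profiles[i].cell_id for i in np.asarray(ordering)],
                       fontsize=6)
    ax.set_xlabel("bins (genome order)")
    cbar = fig.colorbar(im, ax=ax, ticks=range(c_max + 1))
    cbar.set_label("copy number")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
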