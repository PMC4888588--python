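"""Aneuploidy and karyotype-heterogeneity scores for a cell population.

Aneuploidy D measures how far a population's copy-number states diverge
from the baseline euploid state: per bin, the mean absolute deviation of
the called state from the chromosome's baseline ploidy, averaged over bins
with bin-width weights.

Heterogeneity H measures cell-to-cell karyotype variation: per bin, state
frequencies across cells are tabulated and sorted descending
(n_(1) >= n_(2) >= ...); the bin's contribution is
h = sum_j (j - 1) n_(j) / n_cells, so a clonal population scores 0 and H
grows with both the number and the rarity of minority karyotypes.  H is
the width-weighted average of h over bins.  High D with low H marks clonal
aneuploidy; high H marks ongoing chromosomal instability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BinGrid, GenomeLayout
from .hmm import CopyNumberProfile


@dataclass
class KaryotypeMeasures:
    """Genome-wide and per-chromosome aneuploidy/heterogeneity scores."""

    population_id: str
    aneuploidy: float
    heterogeneity: float
    per_chromosome: pd.DataFrame
    n_cells: int
    bin_weighting: str = "width"

    def to_tsv(self, path) -> None:
        rows = [{"population": self.population_id, "scope": "genome",
                 "aneuploidy": self.aneuploidy,
                 "heterogeneity": self.heterogeneity, "n_cells": self.n_cells}]
        for _, r in self.per_chromosome.iterrows():
            rows.append({"population": self.population_id, "scope": r["chrom"],
                         "aneuploidy": r["aneuploidy"],
                         "heterogeneity": r["heterogeneity"],
                         "n_cells": self.n_cells})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _state_matrix(profiles: list[CopyNumberProfile]) -> tuple[BinGrid, np.ndarray]:
    if not profiles:
        raise ValueError("need at least one profile")
    grid = profiles[0].grid
    for p in profiles[1:]:
        same = p.grid is grid or (
            len(p.grid) == len(grid)
            and np.array_equal(p.grid.starts, grid.starts)
            and np.array_equal(p.grid.ends, grid.ends)
            and np.array_equal(p.grid.chroms, grid.chroms))
        if not same:
            raise ValueError("profiles do not share one bin grid")
    return grid, np.vstack([p.states for p in profiles])


def _scope_mask(grid: BinGrid, scope: str) -> np.ndarray:
    if scope == "genome":
        return np.ones(len(grid), dtype=bool)
    if scope not in grid.layout.names:
        raise ValueError(f"unknown scope {scope!r}")
    return np.asarray(grid.chroms == scope)


def _aneuploidy_per_bin(states: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    return np.abs(states - baseline[None, :]).mean(axis=0)


def _heterogeneity_per_bin(states: np.ndarray) -> np.ndarray:
    n_cells, n_bins = states.shape
    h = np.empty(n_bins)
    for i in range(n_bins):
        counts = np.bincount(states[:, i])
        counts = np.sort(counts[counts > 0])[::-1]
        h[i] = float(np.arange(len(counts)) @ counts) / n_cells
    return h


def aneuploidy_score(profiles: list[CopyNumberProfile],
                     layout: GenomeLayout | None = None,
                     scope: str = "genome") -> float:
    """Width-weighted mean over bins of the mean |state - baseline ploidy|."""
    grid, states = _state_matrix(profiles)
    layout = layout or grid.layout
    baseline = np.array([layout.ploidy_of(c) for c in grid.chroms], dtype=float)
    mask = _scope_mask(grid, scope)
    w = grid.widths[mask].astype(float)
    d = _aneuploidy_per_bin(states[:, mask], baseline[mask])
    return float((w * d).sum() / w.sum())


def heterogeneity_score(profiles: list[CopyNumberProfile],
                        scope: str = "genome") -> float:
    """Width-weighted mean of the rank-weighted state tabulation per bin.

    A single cell (or any clonal population) scores exactly 0.
    """
    grid, states = _state_matrix(profiles)
    if states.shape[0] < 2:
        return 0.0
    mask = _scope_mask(grid, scope)
    w = grid.widths[mask].astype(float)
    h = _heterogeneity_per_bin(states[:, mask])
    return float((w * h).sum() / w.sum())


def per_chromosome_measures(profiles: list[CopyNumberProfile],
                            layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Per-chromosome (D_chr, H_chr) table in chromosome order."""
    grid, states = _state_matrix(profiles)
    layout = layout or grid.layout
    baseline = np.array([layout.ploidy_of(c) for c in grid.chroms], dtype=float)
    d = _aneuploidy_per_bin(states, baseline)
    h = (_heterogeneity_per_bin(states) if states.shape[0] >= 2
         else np.zeros(states.shape[1]))
    w = grid.widths.astype(float)
    rows = []
    slices = grid.chrom_slices()
    for chrom in layout.names:
        sl = slices.get(chrom)
        if sl is None:
            continue
        ws = w[sl]
        rows.append({
            "chrom": chrom,
            "aneuploidy": float((ws * d[sl]).sum() / ws.sum()),
            "heterogeneity": float((ws * h[sl]).sum() / ws.sum()),
            "width": float(ws.sum()),
        })
    return pd.DataFrame(rows)


def karyotype_measures(profiles: list[CopyNumberProfile],
                       layout: GenomeLayout | None = None,
                       population_id: str = "population") -> KaryotypeMeasures:
    """Genome-wide and per-chromosome scores for a (QC-passing) population."""
    per_chrom = per_chromosome_measures(profiles, layout)
    return KaryotypeMeasures(
        population_id=population_id,
        aneuploidy=aneuploidy_score(profiles, layout, "genome"),
        heterogeneity=heterogeneity_score(profiles, "genome"),
        per_chromosome=per_chrom,
        n_cells=len(profiles),
    )
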