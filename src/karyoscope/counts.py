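"""Per-cell read counting over a bin grid and GC-bias correction."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinGrid

logger = logging.getLogger(__name__)


@dataclass
class CellCounts:
    """One cell's per-bin read counts.

    ``raw`` are integer counts of analysed reads per bin; ``corrected`` is
    the GC-corrected real-valued version (None until :func:`gc_correct` has
    run).  ``discarded`` tallies qualifying reads that fell outside every
    bin, so ``raw.sum() + discarded`` equals the number of qualifying reads
    in the library.
    """

    cell_id: str
    grid: BinGrid
    raw: np.ndarray
    corrected: np.ndarray | None = None
    discarded: int = 0

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=np.int64)
        if len(self.raw) != len(self.grid):
            raise ValueError("counts length does not match number of bins")
        if np.any(self.raw < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total_reads(self) -> int:
        return int(self.raw.sum())

    @property
    def analysis_counts(self) -> np.ndarray:
        """Corrected counts when available, else raw (float)."""
        return self.corrected if self.corrected is not None else self.raw.astype(float)

    def to_dataframe(self) -> pd.DataFrame:
        df = self.grid.to_dataframe()[["chrom", "start", "end"]].copy()
        df.insert(0, "cell", self.cell_id)
        df["raw"] = self.raw
        df["corrected"] = self.corrected if self.corrected is not None else np.nan
        return df

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, grid: BinGrid) -> "CellCounts":
        df = pd.read_csv(path, sep="\t")
        if len(df) != len(grid):
            raise ValueError("TSV row count does not match grid")
        corrected = df["corrected"].to_numpy(dtype=float)
        if np.all(np.isnan(corrected)):
            corrected = None
        return cls(str(df["cell"].iloc[0]), grid, df["raw"].to_numpy(np.int64),
                   corrected=corrected)


def count_reads(alignment_file, grid: BinGrid, min_mapq: int = 10,
                discard_duplicates: bool = True, cell_id: str | None = None) -> CellCounts:
    """Count qualifying reads per bin from a BAM/SAM file.

    A read qualifies if it is primary, mapped, non-duplicate (when
    ``discard_duplicates``), has MAPQ >= ``min_mapq`` and — for paired
    libraries — is the first in its pair (single-end semantics).  Each
    qualifying read is assigned to the bin containing its leftmost mapped
    base; qualifying reads outside all bins go to the discard tally.
    """
    import pysam

    if len(grid) == 0:
        raise ValueError("grid is empty")
    slices = grid.chrom_slices()
    layout_chroms = set(grid.layout.names)
    counts = np.zeros(len(grid), dtype=np.int64)
    discarded = 0
    n_mapped = 0
    with pysam.AlignmentFile(str(alignment_file), check_sq=False) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name not in layout_chroms:
                raise ValueError(
                    f"read reference {read.reference_name!r} not in genome layout")
            n_mapped += 1
            if discard_duplicates and read.is_duplicate:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if read.is_paired and not read.is_read1:
                continue
            chrom, pos = read.reference_name, read.reference_start
            sl = slices.get(chrom)
            if sl is None:
                discarded += 1
                continue
            s, e = grid.starts[sl], grid.ends[sl]
            j = int(np.searchsorted(s, pos, side="right")) - 1
            if j >= 0 and pos < e[j]:
                counts[sl.start + j] += 1
            else:
                discarded += 1
    if n_mapped == 0:
        logger.warning("%s contains no mapped reads; all-zero counts", alignment_file)
    if cell_id is None:
        cell_id = str(alignment_file)
    return CellCounts(cell_id, grid, counts, discarded=discarded)


def _fit_gc_curve(counts: np.ndarray, gc: np.ndarray,
                  stratum_width: float = 0.01, min_bins: int = 5):
    """OLS quadratic of stratum-mean count vs GC, over 0.01-wide GC strata
    holding at least ``min_bins`` bins.  Returns polynomial coefficients
    (highest degree first) or None when too few strata support a fit."""
    strata = np.floor(gc / stratum_width).astype(int)
    xs, ys = [], []
    for u in np.unique(strata):
        sel = strata == u
        if sel.sum() >= min_bins:
            xs.append(gc[sel].mean())
            ys.append(counts[sel].mean())
    if len(xs) < 3:
        return None
    return np.polyfit(np.asarray(xs), np.asarray(ys), deg=2)


def gc_correct(cell: CellCounts, grid: BinGrid | None = None) -> CellCounts:
    """Correct GC bias: x̃_i = x_i · mean(x) / f(g_i).

    ``f`` is a quadratic fitted to stratum-mean counts vs GC (strata of
    width 0.01 with >= 5 bins).  Bins whose fitted value is non-positive
    keep their raw count.  The remaining corrected counts are rescaled by a
    single global factor so the corrected mean equals the raw mean exactly.
    Requires >= 50 bins with nonzero counts and a known GC for every bin.
    """
    grid = grid if grid is not None else cell.grid
    x = cell.raw.astype(float)
    if np.all(x == 0):
        logger.warning("all-zero counts for %s; no GC fit attempted", cell.cell_id)
        return CellCounts(cell.cell_id, grid, cell.raw, corrected=np.zeros_like(x),
                          discarded=cell.discarded)
    if int((x > 0).sum()) < 50:
        raise ValueError("gc_correct needs >= 50 bins with nonzero counts")
    gc = np.asarray(grid.gc, dtype=float)
    if np.any(~np.isfinite(gc)):
        raise ValueError("GC fraction unknown for some bins; annotate the grid first")

    coeffs = _fit_gc_curve(x, gc)
    if coeffs is None:
        logger.warning("too few GC strata for %s; counts left uncorrected", cell.cell_id)
        corrected = x.copy()
    else:
        f = np.polyval(coeffs, gc)
        ok = f > 0
        corrected = x.copy()
        corrected[ok] = x[ok] * x.mean() / f[ok]
        # mean preservation: rescale the fitted part so sum(corrected) == sum(raw)
        target = x.sum() - x[~ok].sum()
        got = corrected[ok].sum()
        if got > 0 and target > 0:
            corrected[ok] *= target / got
    return CellCounts(cell.cell_id, grid, cell.raw, corrected=corrected,
                      discarded=cell.discarded)
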