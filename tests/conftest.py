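import numpy as np
import pytest

from karyoscope.genome import BinGrid, GenomeLayout
from karyoscope.hmm import CopyNumberProfile


def make_grid(chrom_bins: dict[str, int], width: int = 1_000_000,
              gc=None, ploidy=None) -> BinGrid:
    """Uniform-width grid with the given number of bins per chromosome."""
    names = tuple(chrom_bins)
    lengths = tuple(n * width for n in chrom_bins.values())
    layout = GenomeLayout(names, lengths, dict(ploidy or {}))
    chroms, starts, ends = [], [], []
    for name, n in chrom_bins.items():
        chroms.extend([name] * n)
        starts.extend(range(0, n * width, width))
        ends.extend(range(width, (n + 1) * width, width))
    n_bins = len(chroms)
    gc_arr = np.full(n_bins, 0.42) if gc is None else np.asarray(gc, dtype=float)
    return BinGrid(layout, np.array(chroms, dtype=object),
                   np.array(starts), np.array(ends), gc_arr,
                   np.full(n_bins, float(width)), target_width=width)


def profile_from_states(grid: BinGrid, states, cell_id="cell") -> CopyNumberProfile:
    states = np.asarray(states, dtype=np.int64)
    return CopyNumberProfile(cell_id, grid, states, np.ones(len(states)))


@pytest.fixture
def grid3():
    """Three-chromosome uniform grid (40 + 30 + 30 bins)."""
    return make_grid({"chr1": 40, "chr2": 30, "chr3": 30})
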