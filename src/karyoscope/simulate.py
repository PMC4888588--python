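"""Synthetic single-cell WGS cohorts with known karyotypes.

Emulates the data a chromosomally unstable (CIN) cell population produces:
every cell starts from a clonal base karyotype, optionally undergoes
whole-genome duplication, then acquires a Poisson number of
whole-chromosome (or, optionally, segmental) gain/loss events — the
mis-segregation model.  Per-bin read counts are drawn negative-binomially
with means proportional to copy number times bin width, with optional
multiplicative GC bias, matching the emission family the caller fits.

Default scenario: a ~2.6 Gb genome in ~2,600 one-megabase bins, 40 cells,
130,000 reads per cell (~50 reads per disomic bin) and a per-cell
mis-segregation rate q = 0.1.  Everything is bit-exactly reproducible from
(parameters, seed); each cell gets its own counter-derived RNG stream so
results are independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import CellCounts
from .genome import BinGrid, GenomeLayout
from .hmm import CopyNumberProfile

_KARYO_STREAM = 11
_COUNT_STREAM = 23
_GC_STREAM = 37


def synthetic_layout(n_chrom: int = 20, total_length: int = 2_600_000_000,
                     ploidy: dict | None = None) -> GenomeLayout:
    """Mouse-scale synthetic genome: n chromosomes with linearly decreasing
    lengths summing to ``total_length``."""
    names = tuple(f"chr{i + 1}" for i in range(n_chrom))
    raw = np.linspace(1.6, 0.6, n_chrom)
    lengths = np.round(raw / raw.sum() * total_length).astype(np.int64)
    lengths[-1] += total_length - lengths.sum()
    return GenomeLayout(names, tuple(int(x) for x in lengths), dict(ploidy or {}))


def simulate_grid(layout: GenomeLayout, bin_width: int = 1_000_000,
                  seed: int = 0, gc_mean: float = 0.42,
                  gc_sd: float = 0.05) -> BinGrid:
    """Near-uniform grid with per-bin GC drawn from a Beta distribution
    (mean ~0.42, sd ~0.05 — a mammalian-like GC spread).

    Each chromosome is split into round(length / bin_width) equal-width
    bins (no short remainder bin), mirroring what mass-equalising binning
    produces on a uniformly mappable genome.
    """
    chroms, starts, ends = [], [], []
    for chrom, length in zip(layout.names, layout.lengths):
        n = max(1, round(length / bin_width))
        edges = np.round(np.linspace(0, length, n + 1)).astype(np.int64)
        chroms.extend([chrom] * n)
        starts.append(edges[:-1])
        ends.append(edges[1:])
    starts = np.concatenate(starts)
    ends = np.concatenate(ends)
    rng = np.random.default_rng(np.random.SeedSequence([seed, _GC_STREAM]))
    nu = gc_mean * (1 - gc_mean) / gc_sd**2 - 1
    gc = rng.beta(gc_mean * nu, (1 - gc_mean) * nu, size=len(starts))
    mass = (ends - starts).astype(float)
    return BinGrid(layout, np.array(chroms, dtype=object), starts, ends, gc, mass,
                   target_width=bin_width)


@dataclass
class CohortTruth:
    """Ground-truth per-bin states and the parameters that generated them."""

    layout: GenomeLayout
    grid: BinGrid
    states: np.ndarray            # (n_cells, n_bins) int
    cell_ids: list[str]
    params: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.states.shape[0]

    def profile(self, i: int) -> CopyNumberProfile:
        """The i-th cell's truth as a decoded-profile object."""
        return CopyNumberProfile(self.cell_ids[i], self.grid,
                                 self.states[i].copy(),
                                 np.ones(self.states.shape[1]))

    def profiles(self) -> list[CopyNumberProfile]:
        return [self.profile(i) for i in range(self.n_cells)]

    def to_tsv(self, path) -> None:
        df = self.grid.to_dataframe()[["chrom", "start", "end"]]
        out = pd.concat([df, pd.DataFrame(self.states.T, columns=self.cell_ids)],
                        axis=1)
        out.to_csv(path, sep="\t", index=False)


def simulate_karyotypes(layout: GenomeLayout, n_cells: int = 40,
                        base_karyotype: dict[str, int] | None = None,
                        q: float = 0.1, wgd_fraction: float = 0.0,
                        seed: int = 0, c_max: int = 10,
                        grid: BinGrid | None = None,
                        segmental_rate: float = 0.0) -> CohortTruth:
    """Clonal base karyotype + per-cell mis-segregation events.

    Each cell: with probability ``wgd_fraction`` all states double (capped
    at c_max); then Poisson(q * n_chrom) events each add or subtract one
    copy (equiprobable) of a uniformly chosen chromosome, clipped to
    [0, c_max].  With ``segmental_rate`` > 0, an event instead hits a
    chromosome suffix from a uniform breakpoint bin.  Event draws do not
    depend on the current state, so two cohorts simulated from the same
    seed but different base karyotypes receive identical event sequences.
    """
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    if grid is None:
        grid = simulate_grid(layout, seed=seed)
    base = {c: layout.ploidy_of(c) for c in layout.names}
    if base_karyotype:
        base.update(base_karyotype)
    if any(s > c_max for s in base.values()):
        raise ValueError("base karyotype state exceeds c_max")
    if any(s < 0 for s in base.values()):
        raise ValueError("base karyotype state must be >= 0")
    slices = grid.chrom_slices()
    chrom_names = [c for c in layout.names if c in slices]
    n_chrom = len(chrom_names)
    base_states = np.empty(len(grid), dtype=np.int64)
    for c, sl in slices.items():
        base_states[sl] = base[c]
    states = np.empty((n_cells, len(grid)), dtype=np.int64)
    for i in range(n_cells):
        rng = np.random.default_rng(np.random.SeedSequence([seed, _KARYO_STREAM, i]))
        s = base_states.copy()
        if rng.random() < wgd_fraction:
            s = np.minimum(2 * s, c_max)
        n_events = rng.poisson(q * n_chrom)
        for _ in range(n_events):
            ci = int(rng.integers(n_chrom))
            delta = 1 if rng.random() < 0.5 else -1
            sl = slices[chrom_names[ci]]
            if segmental_rate > 0 and rng.random() < segmental_rate:
                bp = int(rng.integers(sl.stop - sl.start))
                target = slice(sl.start + bp, sl.stop)
            else:
                target = sl
            s[target] = np.clip(s[target] + delta, 0, c_max)
        states[i] = s
    params = dict(n_cells=n_cells, q=q, wgd_fraction=wgd_fraction, seed=seed,
                  c_max=c_max, segmental_rate=segmental_rate,
                  base_karyotype=dict(base))
    return CohortTruth(layout, grid, states,
                       [f"cell_{i:03d}" for i in range(n_cells)], params)


def flat_gc_bias(g):
    return np.ones_like(np.asarray(g, dtype=float))


def linear_gc_bias(slope: float = 2.0, center: float = 0.4):
    """Multiplicative bias b(g) = 1 + slope * (g - center), floored at 0.05."""
    def bias(g):
        return np.clip(1.0 + slope * (np.asarray(g, dtype=float) - center), 0.05, None)
    return bias


def quadratic_gc_bias(strength: float = 4.0, optimum: float = 0.42):
    """Unimodal bias peaking at the GC optimum — the canonical GC-bias shape."""
    def bias(g):
        return np.clip(1.0 - strength * (np.asarray(g, dtype=float) - optimum) ** 2,
                       0.05, None)
    return bias


def simulate_counts(truth: CohortTruth, reads_per_cell: int = 130_000,
                    dispersion: float = 20.0, gc_bias=None,
                    seed: int = 0) -> list[CellCounts]:
    """Draw per-bin NB counts for every cell of a cohort.

    Bin means are proportional to state * width (times the GC bias when
    given), rescaled so the expected total equals ``reads_per_cell``.  The
    NB size parameter is ``dispersion * state``, matching the tied emission
    family of the copy-number HMM; ``dispersion = inf`` gives Poisson
    counts.  State-0 bins emit exactly zero.
    """
    if reads_per_cell <= 0:
        raise ValueError("reads_per_cell must be positive")
    if not dispersion > 0:
        raise ValueError("dispersion must be positive")
    grid = truth.grid
    w = grid.widths.astype(float)
    bias = np.asarray(gc_bias(grid.gc), dtype=float) if gc_bias is not None else \
        np.ones(len(grid))
    cells = []
    for i in range(truth.n_cells):
        s = truth.states[i].astype(float)
        if np.all(s == 0):
            raise ValueError(f"all-zero karyotype for cell {i}")
        mean = s * w * bias
        mean *= reads_per_cell / mean.sum()
        rng = np.random.default_rng(np.random.SeedSequence([seed, _COUNT_STREAM, i]))
        counts = np.zeros(len(grid), dtype=np.int64)
        nz = mean > 0
        if np.isinf(dispersion):
            counts[nz] = rng.poisson(mean[nz])
        else:
            size = dispersion * s[nz]
            p = size / (size + mean[nz])
            counts[nz] = rng.negative_binomial(size, p)
        cells.append(CellCounts(truth.cell_ids[i], grid, counts))
    return cells


def evaluate_calls(profiles: list[CopyNumberProfile], truth: CohortTruth) -> dict:
    """Compare decoded profiles against the simulation truth.

    Returns per-cell per-bin accuracies, per-chromosome modal-state
    accuracy, and a confusion matrix (rows = truth state, columns = call).
    """
    from .cohort import modal_chromosome_states

    if len(profiles) != truth.n_cells:
        raise ValueError("number of profiles does not match truth")
    n_bins = truth.states.shape[1]
    c_max = int(truth.params.get("c_max", 10))
    confusion = np.zeros((c_max + 1, c_max + 1), dtype=np.int64)
    per_bin_acc = np.empty(truth.n_cells)
    modal_hits = 0
    modal_total = 0
    for i, prof in enumerate(profiles):
        if len(prof.states) != n_bins:
            raise ValueError("profile/truth shape mismatch")
        t = truth.states[i]
        per_bin_acc[i] = float(np.mean(prof.states == t))
        np.add.at(confusion, (t, np.clip(prof.states, 0, c_max)), 1)
        called = modal_chromosome_states(prof)
        true_modal = modal_chromosome_states(truth.profile(i))
        for chrom, st in true_modal.items():
            modal_total += 1
            modal_hits += int(called[chrom] == st)
    return {
        "per_bin_accuracy": per_bin_acc,
        "median_per_bin_accuracy": float(np.median(per_bin_acc)),
        "per_chromosome_modal_accuracy": modal_hits / modal_total,
        "confusion": pd.DataFrame(confusion,
                                  index=[f"true_{i}" for i in range(c_max + 1)],
                                  columns=[f"called_{i}" for i in range(c_max + 1)]),
    }


# ---------------------------------------------------------------------------
# minimal SAM output, for exercising the read counter without real alignments

def write_sam(path, layout: GenomeLayout, reads) -> None:
    """Write a minimal coordinate-sorted SAM file.

    ``reads`` is an iterable of (qname, flag, chrom, pos0, mapq) with
    0-based positions; sequence and qualities are omitted ('*').
    """
    reads = sorted(reads, key=lambda r: (layout.names.index(r[2]), r[3]))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, length in zip(layout.names, layout.lengths):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for qname, flag, chrom, pos0, mapq in reads:
            fh.write(f"{qname}\t{flag}\t{chrom}\t{pos0 + 1}\t{mapq}\t50M\t*\t0\t0\t*\t*\n")


def sam_from_counts(cell: CellCounts, path, seed: int = 0, mapq: int = 60) -> None:
    """Emit one 50 bp single-end read per counted read, placed uniformly
    within its bin, as a SAM file."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 53]))
    grid = cell.grid
    reads = []
    k = 0
    for i in range(len(grid)):
        n = int(cell.raw[i])
        if n == 0:
            continue
        hi = max(int(grid.starts[i]) + 1, int(grid.ends[i]) - 50)
        pos = rng.integers(grid.starts[i], hi, size=n)
        chrom = str(grid.chroms[i])
        for p in pos:
            reads.append((f"{cell.cell_id}_r{k}", 0, chrom, int(p), mapq))
            k += 1
    write_sam(path, grid.layout, reads)
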