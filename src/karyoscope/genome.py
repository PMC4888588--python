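"""Genome layout and mappability-based variable-width binning.

Low-coverage single-cell WGS is analysed in large genomic bins.  Fixed-width
bins inherit the genome's mappability structure as spurious coverage
variation, so bins are instead sized to hold an equal amount of *mappable
mass* -- either reads from a euploid reference alignment or per-base
mappability scores.  Bins then have variable width (averaging the requested
target, 1 Mb by default) but comparable expected read counts on a euploid
genome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_PLOIDY = 2


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names, lengths (bp) and baseline ploidy.

    Baseline ploidy is per chromosome (default disomic everywhere); allosomes
    can be set per sample sex, e.g. ``ploidy={"chrX": 1, "chrY": 1}`` for a
    male library.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    ploidy: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.names) != len(set(self.names)):
            raise ValueError("chromosome names must be unique")
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        if any(p < 1 for p in self.ploidy.values()):
            raise ValueError("baseline ploidy must be >= 1")
        unknown = set(self.ploidy) - set(self.names)
        if unknown:
            raise ValueError(f"ploidy given for unknown chromosomes: {sorted(unknown)}")

    def length_of(self, chrom: str) -> int:
        return self.lengths[self.names.index(chrom)]

    def ploidy_of(self, chrom: str) -> int:
        return self.ploidy.get(chrom, DEFAULT_PLOIDY)

    @classmethod
    def from_chrom_sizes(cls, path, ploidy=None) -> "GenomeLayout":
        """Read a 2-column ``chrom<TAB>length`` text file (UCSC chrom.sizes)."""
        names, lengths = [], []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                chrom, size = line.split()[:2]
                names.append(chrom)
                lengths.append(int(size))
        return cls(tuple(names), tuple(lengths), dict(ploidy or {}))


@dataclass
class BinGrid:
    """Ordered, non-overlapping variable-width bins over a genome.

    Coordinates are 0-based half-open.  ``gc`` is the GC fraction per bin
    (NaN when unannotated) and ``mass`` the mappable mass the bin holds.
    """

    layout: GenomeLayout
    chroms: np.ndarray          # object array, one entry per bin
    starts: np.ndarray          # int64
    ends: np.ndarray            # int64
    gc: np.ndarray              # float64, NaN if unknown
    mass: np.ndarray            # float64
    target_width: int = 1_000_000

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.gc = np.asarray(self.gc, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)
                == len(self.gc) == len(self.mass)):
            raise ValueError("bin arrays must have equal length")
        if np.any(self.starts >= self.ends):
            raise ValueError("bins must satisfy start < end")
        for chrom, sl in self.chrom_slices().items():
            s, e = self.starts[sl], self.ends[sl]
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"bins overlap or are unsorted on {chrom}")
            if e[-1] > self.layout.length_of(chrom):
                raise ValueError(f"bin exceeds chromosome boundary on {chrom}")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous slice of bin indices per chromosome, in genome order."""
        out: dict[str, slice] = {}
        i = 0
        n = len(self.chroms)
        while i < n:
            chrom = self.chroms[i]
            j = i
            while j < n and self.chroms[j] == chrom:
                j += 1
            if chrom in out:
                raise ValueError(f"bins of {chrom} are not contiguous")
            out[chrom] = slice(i, j)
            i = j
        return out

    def baseline_ploidy(self) -> np.ndarray:
        """Per-bin baseline copy number from the layout."""
        return np.array([self.layout.ploidy_of(c) for c in self.chroms], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chroms, "start": self.starts, "end": self.ends,
            "gc": self.gc, "mass": self.mass,
        })

    def to_bed(self, path) -> None:
        """BED with mass in the score column and GC as an extra column."""
        df = self.to_dataframe()
        out = pd.DataFrame({
            "chrom": df["chrom"], "start": df["start"], "end": df["end"],
            "name": [f"bin_{i}" for i in range(len(df))],
            "score": df["mass"], "strand": ".", "gc": df["gc"].round(4),
        })
        out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Mappability sources

class MappabilityTrack:
    """Per-chromosome mappable-mass curve.

    Accepts either per-read point masses (an aligned euploid-reference
    library) or a piecewise-constant per-base track (bedGraph / BigWig);
    both reduce to a cumulative-mass curve M(b) = mass on [0, b).
    """

    def __init__(self):
        self._points: dict[str, np.ndarray] = {}
        self._intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @property
    def chromosomes(self) -> set[str]:
        return set(self._points) | set(self._intervals)

    @classmethod
    def from_read_positions(cls, positions: dict[str, np.ndarray]) -> "MappabilityTrack":
        """Each read contributes unit mass at its leftmost mapped base."""
        t = cls()
        for chrom, pos in positions.items():
            t._points[chrom] = np.sort(np.asarray(pos, dtype=np.int64))
        return t

    @classmethod
    def from_intervals(cls, intervals: dict[str, tuple]) -> "MappabilityTrack":
        """``{chrom: (starts, ends, values)}`` piecewise-constant density."""
        t = cls()
        for chrom, (s, e, v) in intervals.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=float)
            order = np.argsort(s)
            t._intervals[chrom] = (s[order], e[order], v[order])
        return t

    @classmethod
    def from_bedgraph(cls, path) -> "MappabilityTrack":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"], comment="#")
        return cls.from_intervals({
            c: (g["start"].to_numpy(), g["end"].to_numpy(), g["value"].to_numpy())
            for c, g in df.groupby("chrom", sort=False)
        })

    @classmethod
    def from_bigwig(cls, path, layout: GenomeLayout) -> "MappabilityTrack":
        import pyBigWig  # optional at runtime, needed only for .bw input
        bw = pyBigWig.open(str(path))
        intervals = {}
        for chrom in layout.names:
            if chrom not in bw.chroms():
                continue
            ivs = bw.intervals(chrom)
            if ivs:
                s, e, v = map(np.asarray, zip(*ivs))
                intervals[chrom] = (s, e, v)
        bw.close()
        return cls.from_intervals(intervals)

    @classmethod
    def from_alignment(cls, path, min_mapq: int = 10) -> "MappabilityTrack":
        """Mass curve from a euploid-reference BAM/SAM (one point per read)."""
        import pysam
        positions: dict[str, list[int]] = {}
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for read in af:
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if read.mapping_quality < min_mapq:
                    continue
                positions.setdefault(read.reference_name, []).append(read.reference_start)
        return cls.from_read_positions({c: np.array(p) for c, p in positions.items()})

    def total_mass(self, chrom: str) -> float:
        if chrom in self._points:
            return float(len(self._points[chrom]))
        s, e, v = self._intervals[chrom]
        return float(np.sum((e - s) * v))

    def boundaries(self, chrom: str, targets: np.ndarray) -> np.ndarray:
        """Smallest integer b with cumulative mass M(b) >= target, per target."""
        targets = np.asarray(targets, dtype=float)
        if chrom in self._points:
            p = self._points[chrom]
            # M(b) = #(reads with position < b); crossing read is index ceil(t)-1
            idx = np.ceil(targets).astype(np.int64) - 1
            idx = np.clip(idx, 0, len(p) - 1)
            return p[idx] + 1
        s, e, v = self._intervals[chrom]
        seg_mass = (e - s) * v
        cum = np.concatenate([[0.0], np.cumsum(seg_mass)])
        out = np.empty(len(targets), dtype=np.int64)
        for k, t in enumerate(targets):
            j = int(np.searchsorted(cum, t, side="left")) - 1
            j = min(max(j, 0), len(s) - 1)
            while cum[j + 1] < t and j < len(s) - 1:
                j += 1
            need = t - cum[j]
            b = s[j] + (math.ceil(need / v[j]) if v[j] > 0 else (e[j] - s[j]))
            out[k] = min(b, e[j])
        return out


def build_variable_bins(mappability_source: MappabilityTrack,
                        layout: GenomeLayout,
                        target_width: int = 1_000_000) -> BinGrid:
    """Partition each chromosome into bins of equal mappable mass.

    The number of bins per chromosome is ``round(length / target_width)``
    (minimum 1); boundaries are placed greedily left-to-right at the first
    base where the cumulative mass reaches each bin's quota, so every bin
    holds approximately ``total mass / n_bins``.  The last bin absorbs the
    remainder and bins jointly span the chromosome.

    Raises ``ValueError`` if a chromosome of the layout is absent from the
    mappability source; a chromosome with zero total mass emits zero bins
    (with a logged warning).
    """
    if target_width < 10_000:
        raise ValueError("target_width must be >= 10 kb")
    chroms_l, starts_l, ends_l, mass_l = [], [], [], []
    available = mappability_source.chromosomes
    for chrom, length in zip(layout.names, layout.lengths):
        if chrom not in available:
            raise ValueError(f"chromosome {chrom!r} absent from mappability source")
        total = mappability_source.total_mass(chrom)
        if total <= 0:
            logger.warning("chromosome %s has zero mappable mass; emitting no bins", chrom)
            continue
        n_bins = max(1, round(length / target_width))
        quota = total / n_bins
        inner = mappability_source.boundaries(chrom, quota * np.arange(1, n_bins))
        inner = np.clip(inner, 1, length - 1)
        bounds = np.concatenate([[0], inner, [length]])
        # greedy placement can collide on sparse mass; drop degenerate bins
        keep = np.diff(bounds) > 0
        s = bounds[:-1][keep]
        e = bounds[1:][keep]
        chroms_l.extend([chrom] * len(s))
        starts_l.append(s)
        ends_l.append(e)
        m = np.full(len(s), total / max(len(s), 1))
        mass_l.append(m)
    starts = np.concatenate(starts_l) if starts_l else np.array([], dtype=np.int64)
    ends = np.concatenate(ends_l) if ends_l else np.array([], dtype=np.int64)
    mass = np.concatenate(mass_l) if mass_l else np.array([], dtype=float)
    return BinGrid(layout, np.array(chroms_l, dtype=object), starts, ends,
                   np.full(len(starts), np.nan), mass, target_width=target_width)


def apply_blacklist(grid: BinGrid, blacklist) -> BinGrid:
    """Remove bins overlapping blacklist intervals by >= 50 % of their width.

    ``blacklist`` is an iterable of ``(chrom, start, end)`` (0-based
    half-open) or a BED path.  Intervals on chromosomes unknown to the grid
    are logged and skipped.  Returns a new grid; removals are logged.
    """
    if isinstance(blacklist, (str, bytes)) or hasattr(blacklist, "read"):
        df = pd.read_csv(blacklist, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
        blacklist = list(df.itertuples(index=False, name=None))
    overlap = np.zeros(len(grid), dtype=float)
    slices = grid.chrom_slices()
    known = set(grid.layout.names)
    for chrom, bs, be in blacklist:
        if chrom not in known:
            logger.warning("blacklist interval on unknown chromosome %s skipped", chrom)
            continue
        if chrom not in slices:
            continue
        sl = slices[chrom]
        s, e = grid.starts[sl], grid.ends[sl]
        ov = np.clip(np.minimum(e, be) - np.maximum(s, bs), 0, None)
        overlap[sl] += ov
    keep = overlap < 0.5 * grid.widths
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("blacklist removed %d of %d bins", n_removed, len(grid))
    return BinGrid(grid.layout, grid.chroms[keep], grid.starts[keep],
                   grid.ends[keep], grid.gc[keep], grid.mass[keep],
                   target_width=grid.target_width)


def annotate_gc(grid: BinGrid, fasta_path) -> BinGrid:
    """Fill per-bin GC fraction from a reference FASTA (in place; returns grid)."""
    from pysam import FastaFile
    with FastaFile(str(fasta_path)) as fa:
        for i in range(len(grid)):
            seq = fa.fetch(str(grid.chroms[i]), int(grid.starts[i]), int(grid.ends[i])).upper()
            acgt = sum(seq.count(b) for b in "ACGT")
            grid.gc[i] = (seq.count("G") + seq.count("C")) / acgt if acgt else np.nan
    return grid
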