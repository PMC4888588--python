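"""End-to-end pipeline: alignments -> bins -> counts -> HMM fits -> QC ->
karyotype scores -> heatmap, with every stage's artefact written to disk."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import cluster_cells, genomewide_heatmap, pseudobulk
from .config import RunConfig
from .counts import CellCounts, count_reads, gc_correct
from .genome import (BinGrid, GenomeLayout, MappabilityTrack, annotate_gc,
                     apply_blacklist, build_variable_bins)
from .hmm import CopyNumberProfile, fit_cell
from .karyotype import karyotype_measures
from .qc import cluster_and_select, collect_metrics, write_qc_report

logger = logging.getLogger(__name__)


def grid_from_bed(path, layout: GenomeLayout, target_width: int = 1_000_000) -> BinGrid:
    """Read a grid written by :meth:`BinGrid.to_bed`."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand", "gc"])
    return BinGrid(layout, df["chrom"].to_numpy(object),
                   df["start"].to_numpy(np.int64), df["end"].to_numpy(np.int64),
                   df["gc"].to_numpy(float), df["score"].to_numpy(float),
                   target_width=target_width)


def load_profile_bed(path, grid: BinGrid, cell_id: str | None = None) -> CopyNumberProfile:
    """Read a per-cell profile BED written by :meth:`CopyNumberProfile.to_bed`."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score"])
    if len(df) != len(grid):
        raise ValueError("profile BED does not match grid")
    return CopyNumberProfile(cell_id or Path(path).stem, grid,
                             df["name"].to_numpy(np.int64),
                             df["score"].to_numpy(float) / 1000.0)


def _load_mappability(cfg: RunConfig, layout: GenomeLayout) -> MappabilityTrack:
    src = cfg.mappability
    if src == "uniform":
        return MappabilityTrack.from_intervals({
            c: (np.array([0]), np.array([l]), np.array([1.0]))
            for c, l in zip(layout.names, layout.lengths)})
    src = str(src)
    if src.endswith((".bw", ".bigwig", ".bigWig")):
        return MappabilityTrack.from_bigwig(src, layout)
    if src.endswith((".bam", ".sam")):
        return MappabilityTrack.from_alignment(src, min_mapq=cfg.min_mapq)
    return MappabilityTrack.from_bedgraph(src)


def _gather_inputs(cfg: RunConfig) -> tuple[list[Path], list[Path]]:
    d = Path(cfg.alignments_dir)
    alns = sorted(list(d.glob("*.sam")) + list(d.glob("*.bam")))
    tsvs = sorted(d.glob("*.tsv"))
    return alns, tsvs


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write its artefacts under ``config.output_dir``.

    Deterministic given the config (all randomness flows from
    ``config.seed``).  Input cells come from BAM/SAM files in
    ``alignments_dir``, or — when none are present — from binned-count TSV
    files written by the simulator.
    """
    t_start = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"karyoscope {__version__}"]
    for k, v in vars(config).items():
        log_lines.append(f"param {k} = {v}")

    def stage(name):
        log_lines.append(f"stage {name} at {time.time() - t_start:.2f}s")

    if config.chrom_sizes is None or config.alignments_dir is None:
        raise ValueError("config needs chrom_sizes and alignments_dir")
    layout = GenomeLayout.from_chrom_sizes(config.chrom_sizes, ploidy=config.ploidy)

    stage("binning")
    track = _load_mappability(config, layout)
    grid = build_variable_bins(track, layout, target_width=config.target_width)
    if config.blacklist:
        n_before = len(grid)
        grid = apply_blacklist(grid, config.blacklist)
        log_lines.append(f"blacklist removed {n_before - len(grid)} bins")
    if config.fasta:
        grid = annotate_gc(grid, config.fasta)
    grid.to_bed(out / "bins.bed")

    stage("counting")
    alns, tsvs = _gather_inputs(config)
    cells: list[CellCounts] = []
    counts_dir = out / "counts"
    counts_dir.mkdir(exist_ok=True)
    if alns:
        for path in alns:
            cells.append(count_reads(path, grid, min_mapq=config.min_mapq,
                                     discard_duplicates=config.discard_duplicates,
                                     cell_id=path.stem))
    elif tsvs:
        # simulator output: counts on its own grid definition
        for path in tsvs:
            df = pd.read_csv(path, sep="\t")
            if len(df) != len(grid):
                raise ValueError(f"{path} does not match the built grid")
            cells.append(CellCounts(str(df["cell"].iloc[0]), grid,
                                    df["raw"].to_numpy(np.int64)))
    else:
        raise ValueError(f"no alignment or counts files in {config.alignments_dir}")

    stage("gc_correction")
    have_gc = bool(np.all(np.isfinite(grid.gc)))
    if have_gc:
        cells = [gc_correct(c, grid) for c in cells]
    else:
        log_lines.append("no GC annotation; correction skipped")
    for c in cells:
        c.to_tsv(counts_dir / f"{c.cell_id}.tsv")

    stage("hmm_fits")
    profiles_dir = out / "profiles"
    profiles_dir.mkdir(exist_ok=True)
    fits, profiles = [], []
    for c in cells:
        try:
            res, prof = fit_cell(c, c_max=config.c_max,
                                 most_frequent_state=config.most_frequent_state,
                                 tol=config.tol, max_iter=config.max_iter,
                                 n_restarts=config.n_restarts, seed=config.seed)
        except Exception as err:
            raise RuntimeError(f"stage hmm_fits failed for cell {c.cell_id}: {err}") from err
        fits.append(res)
        profiles.append(prof)
        prof.to_bed(profiles_dir / f"{c.cell_id}.bed")
        res.save_params(profiles_dir / f"{c.cell_id}.params.txt")
    seg = pd.concat([p.segments.assign(cell=p.cell_id) for p in profiles])
    seg.to_csv(out / "segments.tsv", sep="\t", index=False)

    stage("qc")
    metrics = [collect_metrics(c, f, p) for c, f, p in zip(cells, fits, profiles)]
    metrics, _ = cluster_and_select(metrics, k_max=config.k_max, seed=config.seed)
    write_qc_report(metrics, out / "qc_report.tsv")
    selected = [p for p, m in zip(profiles, metrics) if m.selected]
    log_lines.append(f"qc selected {len(selected)} of {len(profiles)} libraries")

    stage("scores")
    scored = selected if selected else profiles
    measures = karyotype_measures(scored, layout, population_id=out.name)
    measures.to_tsv(out / "scores.tsv")
    measures.per_chromosome.to_csv(out / "per_chromosome_scores.tsv",
                                   sep="\t", index=False)

    stage("cohort_outputs")
    bulk = pseudobulk(cells)
    bulk.to_bedgraph(out / "pseudobulk.bedgraph")
    order, _, _ = cluster_cells(scored) if len(scored) > 1 else (
        np.arange(len(scored)), None, None)
    with open(out / "cluster_order.txt", "w") as fh:
        for i in np.asarray(order):
            fh.write(scored[i].cell_id + "\n")
    genomewide_heatmap(scored, ordering=order, path=out / "heatmap.png",
                       c_max=config.c_max)

    stage("done")
    config.to_file(out / "run_config.txt")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
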