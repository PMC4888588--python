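"""Library quality control: per-cell quality measures and cluster selection.

Single-cell WGS libraries vary widely in quality; poor libraries produce
noisy, over-segmented copy-number calls.  Four measures summarise each
library -- spikiness (bin-to-bin count variation), the fitted model's
loglikelihood, the number of copy-number segments, and the Bhattacharyya
distance between neighbouring emission distributions -- and libraries are
clustered on them (1 to 3 clusters); the best-scoring cluster is kept for
downstream analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import nbinom, rankdata
from sklearn.metrics import silhouette_score

from .counts import CellCounts
from .hmm import CopyNumberHMMResults, CopyNumberProfile, EmissionModel

logger = logging.getLogger(__name__)


@dataclass
class QualityMetrics:
    """Per-library QC measures plus cluster label and selection flag."""

    cell_id: str
    spikiness: float
    loglik: float
    n_bins: int
    n_segments: int
    bhattacharyya: float
    total_reads: int
    cluster: int = -1
    selected: bool = False

    @property
    def loglik_per_bin(self) -> float:
        return self.loglik / self.n_bins if self.n_bins else np.nan

    def is_finite(self) -> bool:
        return bool(np.isfinite([self.spikiness, self.loglik,
                                 self.bhattacharyya]).all())


def spikiness(cell: CellCounts) -> float:
    """Sum of absolute successive raw-count differences over the total count.

    Differences are taken in genome order within each chromosome (never
    across a chromosome boundary).  Scale-invariant: s(a*x) = s(x).
    """
    x = cell.raw.astype(float)
    total = x.sum()
    if total <= 0:
        raise ValueError("spikiness undefined for an all-zero library")
    if len(x) < 2:
        raise ValueError("spikiness needs at least 2 bins")
    num = 0.0
    for sl in cell.grid.chrom_slices().values():
        num += np.abs(np.diff(x[sl])).sum()
    return float(num / total)


def count_segments(profile: CopyNumberProfile) -> int:
    """Number of maximal constant-state runs, chromosomes counted separately."""
    return profile.n_segments


def bhattacharyya_distance(model: EmissionModel, states: tuple[int, int] = (1, 2),
                           tail: float = 1e-12) -> float:
    """BD = -ln sum_x sqrt(P_a(x) P_b(x)) between two NB emission states.

    By default the state-1 and state-2 distributions — the closest
    biologically meaningful pair; a large distance means well-separated
    copy-number states.  The sum is truncated where both pmfs have left at
    most ``tail`` cumulative mass.
    """
    a, b = states
    if min(a, b) < 1 or max(a, b) > model.c_max:
        raise ValueError("Bhattacharyya states must be NB states in [1, c_max]")
    ra, rb = a * model.r1, b * model.r1
    hi = int(max(nbinom.ppf(1 - tail, ra, model.p),
                 nbinom.ppf(1 - tail, rb, model.p))) + 1
    x = np.arange(hi + 1)
    bc = np.sum(np.sqrt(nbinom.pmf(x, ra, model.p) * nbinom.pmf(x, rb, model.p)))
    bc = min(bc, 1.0)
    return float(-np.log(bc)) if bc > 0 else np.inf


def collect_metrics(cell: CellCounts, fit: CopyNumberHMMResults,
                    profile: CopyNumberProfile) -> QualityMetrics:
    """Assemble the QC measures for one fitted library."""
    return QualityMetrics(
        cell_id=cell.cell_id,
        spikiness=spikiness(cell),
        loglik=fit.loglik,
        n_bins=len(cell.grid),
        n_segments=count_segments(profile),
        bhattacharyya=bhattacharyya_distance(fit.emission),
        total_reads=cell.total_reads,
    )


def cluster_and_select(metrics: list[QualityMetrics], k_max: int = 3,
                       seed: int = 0, silhouette_floor: float = 0.3
                       ) -> tuple[list[QualityMetrics], int]:
    """Cluster libraries on their QC measures and select the best cluster.

    Features (spikiness, loglikelihood per bin, segment count,
    Bhattacharyya distance) are z-standardised; Ward-linkage hierarchical
    clustering is cut at k in 1..k_max, k chosen by mean silhouette (k = 1
    when the best silhouette is below ``silhouette_floor``).  The selected
    cluster is the one with the best mean rank over (low spikiness, high
    Bhattacharyya distance, few segments, high loglikelihood).  Libraries
    with non-finite measures are rejected up front (cluster -1, never
    selected).  Returns the labelled metrics and the selected cluster id.
    """
    for m in metrics:
        m.cluster = -1
        m.selected = False
    usable = [m for m in metrics if m.is_finite()]
    rejected = len(metrics) - len(usable)
    if rejected:
        logger.info("rejected %d libraries with non-finite QC measures", rejected)
    if len(usable) < 2:
        logger.warning("fewer than 2 usable libraries; selecting all of them")
        for m in usable:
            m.cluster = 0
            m.selected = True
        return metrics, 0

    feats = np.array([[m.spikiness, m.loglik_per_bin, m.n_segments,
                       m.bhattacharyya] for m in usable], dtype=float)
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    z = (feats - mu) / sd

    Z = linkage(z, method="ward")
    best_k, best_sil, best_labels = 1, -np.inf, np.zeros(len(usable), dtype=int)
    for k in range(2, min(k_max, len(usable) - 1) + 1):
        labels = fcluster(Z, k, criterion="maxclust") - 1
        if len(np.unique(labels)) < 2:
            continue
        sil = silhouette_score(z, labels)
        if sil > best_sil:
            best_k, best_sil, best_labels = k, sil, labels
    if best_sil < silhouette_floor:
        best_k, best_labels = 1, np.zeros(len(usable), dtype=int)

    # composite ranking of cluster means: low spikiness, high BD, low
    # segment count, high loglikelihood; best mean rank wins
    ids = np.unique(best_labels)
    means = np.array([feats[best_labels == c].mean(axis=0) for c in ids])
    ranks = np.column_stack([
        rankdata(means[:, 0]),        # spikiness: low is good
        rankdata(-means[:, 1]),       # loglik/bin: high is good
        rankdata(means[:, 2]),        # segments: low is good
        rankdata(-means[:, 3]),       # BD: high is good
    ])
    selected_cluster = int(ids[np.argmin(ranks.mean(axis=1))])

    for m, lab in zip(usable, best_labels):
        m.cluster = int(lab)
        m.selected = bool(lab == selected_cluster)
    return metrics, selected_cluster


def metrics_to_dataframe(metrics: list[QualityMetrics]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell": m.cell_id, "spikiness": m.spikiness, "loglik": m.loglik,
        "loglik_per_bin": m.loglik_per_bin, "n_segments": m.n_segments,
        "bhattacharyya": m.bhattacharyya, "total_reads": m.total_reads,
        "cluster": m.cluster, "selected": m.selected,
    } for m in metrics])


def write_qc_report(metrics: list[QualityMetrics], path) -> None:
    metrics_to_dataframe(metrics).to_csv(path, sep="\t", index=False)
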