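# karyoscope

Copy-number calling and karyotype-heterogeneity scoring for low-coverage
single-cell whole-genome sequencing (scWGS).

Single-cell WGS of tumours and unstable tissues asks two questions bulk
sequencing cannot answer: *what is each cell's karyotype* and *how much do
karyotypes differ between cells* (the signature of ongoing chromosomal
instability, CIN). karyoscope implements the full analysis path for one
library per cell at ~0.01–0.1x coverage:

1. **Variable-width binning** — the genome is partitioned into
   non-overlapping bins of equal *mappable mass* (from a euploid reference
   alignment or a mappability track), averaging a configurable 1 Mb, so a
   euploid genome yields flat expected counts; artefact-prone regions are
   removed with a blacklist.
2. **GC correction** — a quadratic fit of stratum-mean count versus GC
   removes the amplification bias, mean-preservingly.
3. **NB-HMM copy-number calling** — hidden states are integer copy numbers
   0..10 (nullisomy to decasomy). State 0 emits a point mass at zero; state
   c ≥ 1 emits NB(c·r₁, p) (mean c·μ₁ with μ₁ = r₁(1−p)/p), so means and
   variances scale linearly with copy number. Parameters, transition matrix
   and initial distribution are estimated per cell by Baum-Welch EM; every
   bin gets the state maximising its posterior probability.
4. **Library QC** — spikiness Σ|xᵢ₊₁−xᵢ|/Σxᵢ, model loglikelihood, segment
   count and the Bhattacharyya distance between neighbouring emission
   distributions are clustered (Ward, 1–3 clusters) and the best-scoring
   cluster is kept.
5. **Karyotype scores** — aneuploidy D = width-weighted mean over bins of
   mean|ĉ − P| (divergence from baseline ploidy P), and heterogeneity
   H = width-weighted mean of Σⱼ(j−1)n₍ⱼ₎/n over the descending per-bin
   state frequencies n₍₁₎ ≥ n₍₂₎ ≥ …, genome-wide and per chromosome.
6. **Cohort tools** — pseudo-bulk aggregation (showing how bulk masks
   minority subclones), profile clustering, genome-wide heatmaps and
   odd-modal-state detection for separating near-tetraploid cells from G2
   contamination.
7. **Simulator** — a CIN-cohort generator (clonal base karyotype,
   whole-genome duplication, Poisson whole-chromosome mis-segregation, NB
   counts with optional GC bias) providing ground truth for every stage.

## Worked example

```python
import karyoscope as ks

layout = ks.synthetic_layout(n_chrom=10, total_length=1_000_000_000)
grid = ks.simulate_grid(layout, seed=4)
truth = ks.simulate_karyotypes(layout, n_cells=12, q=0.2, seed=4, grid=grid)
cells = ks.simulate_counts(truth, reads_per_cell=50_000, seed=4)

res, profile = ks.fit_cell(cells[0], seed=0)
print(res.summary())

profiles = [ks.fit_cell(c, seed=0)[1] for c in cells]
ev = ks.evaluate_calls(profiles, truth)
print(f"median per-bin accuracy: {ev['median_per_bin_accuracy']:.4f}")
m = ks.karyotype_measures(profiles, layout, population_id="demo")
print(f"aneuploidy D = {m.aneuploidy:.4f}, heterogeneity H = {m.heterogeneity:.4f}")
```

prints

```
Copy-number NB-HMM fit
==================================
                  cell: cell_000
                 c_max: 10
   most_frequent_state: 2
                    r1: 20.4834563899395
                     p: 0.43567841440610605
                   mu1: 26.531625635323266
                loglik: -3774.6682378063215
                n_iter: 4
             converged: True
           state means: 0.0, 26.5, 53.1, 79.6, 106.1, ...

median per-bin accuracy: 0.9990
aneuploidy D = 0.1906, heterogeneity H = 0.2317
```

The fitted per-copy mean μ₁ ≈ 26.5 reads matches the simulated depth
(50,000 reads over ~1,000 bins at mostly two copies); 99.9 % of bins are
decoded to their true copy number; at mis-segregation rate q = 0.2 the
12-cell population shows substantial cell-to-cell heterogeneity (H ≈ 0.23)
alongside moderate net aneuploidy (D ≈ 0.19).

The same pipeline runs from the shell on BAM/SAM input:

```bash
karyoscope simulate --outdir sim --n-cells 12 --q 0.2 --seed 4
karyoscope run --alignments sim/counts --chrom-sizes sim/chrom.sizes --out results
```

`results/` then holds `bins.bed`, per-cell counts and profile BEDs (loadable
in a genome browser), `qc_report.tsv`, `scores.tsv`,
`per_chromosome_scores.tsv`, `pseudobulk.bedgraph` and `heatmap.png`.

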