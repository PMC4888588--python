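# Methods

This note documents the statistical model, the design decisions taken where
the method leaves room, the synthetic-data generator's scope, and the
numerical choices, in the way a maintainer would want them recorded.

## Binning and GC correction

Low-coverage scWGS signal is read counts in large genomic bins. Bins are
sized to hold equal *mappable mass*: either each read of a euploid
reference alignment contributes unit mass at its leftmost mapped base, or a
per-base mappability track contributes its value per base. Both reduce to a
cumulative-mass curve M(b). A chromosome of length L at target width T
(default 1 Mb; minimum 10 kb) gets n = round(L/T) bins (minimum 1); the
k-th boundary is the first base where M(b) ≥ k·(total/n) (greedy
left-to-right placement, ties toward the smaller bin; the last bin absorbs
the remainder). On constant mappability this reduces exactly to fixed-width
binning. A chromosome missing from the mappability source is a hard error;
one with zero mass emits no bins (logged). Blacklisted bins are removed
when blacklist intervals cover ≥ 50 % of the bin's width (overlap
accumulates across intervals). Coordinates are 0-based half-open
throughout; BED is native, SAM positions are converted on input.

Read counting uses single-end semantics matching 50 bp single-end
libraries: primary, mapped, non-duplicate reads with MAPQ ≥ 10 (default)
are assigned to the bin containing the leftmost mapped base; in paired
libraries only first-in-pair reads count. Qualifying reads landing outside
every bin go to a discard tally, so counts + discards equals the qualifying
reads in the file.

GC correction fits an ordinary-least-squares quadratic to stratum-mean
count versus GC over 0.01-wide GC strata holding ≥ 5 bins (stratum-level
fitting keeps outlier bins from dominating; the quadratic matches the
canonical unimodal GC-bias shape). Corrected counts are
x̃ᵢ = xᵢ·mean(x)/f(gᵢ); bins with non-positive fitted value keep their raw
count; the corrected (non-fallback) part is then rescaled by one global
factor so the corrected mean equals the raw mean exactly — the correction
reshapes, never re-weighs, a library. The fit needs ≥ 50 bins with nonzero
counts. Applied twice, the correction is idempotent to within the fit's
residual noise (tested at 2 %).

## The copy-number HMM

Hidden states are integer copy numbers S = {0, …, C_max}, C_max = 10.
Emissions:

* state 0 (nullisomy): a point mass at zero counts. Its log-probability
  for x > 0 is floored at −1e10 rather than −∞ to keep arithmetic finite.
* state c ≥ 1: NB(r_c, p) with the tying rule r_c = c·r₁ and a shared
  success probability p, so mean_c = c·μ₁ (μ₁ = r₁(1−p)/p) and variance_c
  = c·μ₁/p both scale linearly with copy number. Tying keeps the EM
  problem identifiable at single-cell depth, where a per-state free (r, p)
  would overfit states visited by a handful of bins.

GC-corrected (real-valued) counts are rounded to the nearest integer for
emission evaluation — the NB pmf is defined on integers, and rounding keeps
every likelihood exactly computable and testable.

**Initialisation.** μ₁ starts at (smoothed mode of the nonzero counts) /
most_frequent_state; the smoothing window is 10 % of the median nonzero
count. The dispersion starts from a method-of-moments estimate on counts
within 30 % of the mode (p = mean/variance under the NB identity
var = mean/p). The transition matrix starts sticky (self-transition 0.99,
off-diagonal uniform); the initial distribution is uniform.
`most_frequent_state` (default 2) is a *soft* constraint: it only steers
the initialisation, so a near-tetraploid library can be deliberately fitted
"as diploid" and the two fits compared by loglikelihood — with odd-copy
chromosomes present, the forced-disomy fit places their means between
states and loses decisively.

**Baum-Welch.** Chromosomes are independent observation sequences sharing
one parameter set. The E-step uses standard scaled forward-backward (not
log-domain recursions; the contract is the posteriors, which are tested
against exhaustive path enumeration on small instances to 1e-10). Each
row of the emission matrix is rescaled by its maximum before
exponentiation; the maxima are added back into the loglikelihood. The
M-step updates π and A in closed form; (r₁, p) has no closed form and is
updated by bounded 1-D maximisation of the expected NB loglikelihood over
log r₁ (tolerance 1e-8), with p profiled from the expected-mean constraint
p = r₁/(r₁+μ₁), μ₁ = Σγ·x / Σγ·c. Convergence is declared when the
relative loglikelihood improvement is ≤ tol (default 1e-4, max 200
iterations); the check runs after every E-step including the first (the
initial "previous" loglikelihood is −∞), so tol = ∞ performs exactly one
likelihood evaluation and no parameter update. A loglikelihood decrease
beyond 1e-6 relative slack raises an error rather than being papered over;
the convergence flag is reported honestly. Restarts (default 3) perturb
the initial μ₁ multiplicatively by seeded factors in [0.75, 1.3] and keep
the highest-loglikelihood fit; the modest range preserves the ploidy
interpretation the initialisation encodes.

**Decoding.** Each bin takes the state with maximal posterior; exact ties
break toward the lower state (conservative calls). Segments are maximal
constant-state runs within chromosomes and reconstruct the per-bin states
exactly.

The forward-backward inner loops are compiled with numba; at 11 states and
thousands of bins a fit takes tens of milliseconds, which is what makes
the cohort-scale recovery tests and the acceptance script cheap.

## Library QC

Four measures per library: spikiness Σᵢ|xᵢ₊₁−xᵢ|/Σᵢxᵢ on raw counts in
genome order without crossing chromosome boundaries (the canonical
definition for bin-to-bin variation; scale-invariant); the fitted model's
loglikelihood (normalised per bin before clustering so genome size does
not dominate); the number of segments; and the Bhattacharyya distance
BD = −ln Σₓ√(P₁(x)P₂(x)) between the state-1 and state-2 emission
distributions — the closest biologically meaningful pair — summed until
both tails fall below 1e-12. Libraries with non-finite measures are
rejected outright. The rest are z-standardised and clustered by Ward
linkage; the cut k ∈ {1, 2, 3} is chosen by mean silhouette, with k = 1
declared when the best silhouette is below 0.3 (no real structure). The
selected cluster has the best mean rank over (low spikiness, high BD, few
segments, high loglikelihood) — a unit-free composite robust to metric
scales.

## Karyotype scores

With baseline ploidy P per chromosome (default disomy; allosomes
configurable):

* **Aneuploidy** D: per bin, dᵢ = mean over cells of |ĉᵢ − P|; D is the
  bin-width-weighted mean of dᵢ over the scope (genome or one chromosome).
  Divergence is measured in absolute copies, not divided by P; comparisons
  against P-normalised variants must rescale.
* **Heterogeneity** H: per bin, tabulate state frequencies across cells,
  sort descending (n₍₁₎ ≥ n₍₂₎ ≥ …), and set hᵢ = Σⱼ(j−1)·n₍ⱼ₎/n_cells; H
  is the width-weighted mean of hᵢ. H = 0 exactly iff all cells agree
  everywhere, and H grows with both the number and the rarity of minority
  karyotypes; a lone cell scores 0.

Both scores are permutation-invariant in the cells, and the genome-wide
value is exactly the width-weighted mean of the per-chromosome values.
Width weighting is deliberate: variable-width bins cover unequal territory.
Cells failing QC are excluded before scoring.

## Cohort tools

Pseudo-bulk sums raw counts per bin (count-level aggregation — counts are
sufficient for every display here) and scales counts-per-Mb so the
population median equals the median baseline ploidy. A subclone at
fraction f < 0.25 with a ±1 whole-chromosome change moves the chromosome's
expected normalised state by less than 0.25, so its rounded bulk state
equals the majority state while H > 0 on the same cells — the central
bulk-versus-single-cell contrast. Cell clustering uses the width-weighted
mean absolute state difference and average linkage; heatmap rows follow
the dendrogram leaf order. The modal state per chromosome is the
width-weighted majority with ties broken toward even states, conservative
for separating G2 cells (necessarily even) from genuine near-tetraploid
cells; a cell is flagged iff any chromosome's modal state is odd.

## The simulator

`simulate_karyotypes` emulates a CIN population: every cell starts from a
clonal base karyotype; with probability `wgd_fraction` all states double
(capped at C_max); then Poisson(q·n_chrom) whole-chromosome ±1 events hit
uniformly chosen chromosomes (gain/loss equiprobable, clipped to
[0, C_max]). Optional segmental events (uniform breakpoint, ±1 over the
chromosome suffix) sit behind `segmental_rate` and default off — the
default model quantifies heterogeneity on whole-chromosome states. Event
draws are independent of the current state, so cohorts sharing a seed but
differing in base karyotype receive identical event sequences; this is
what makes diploid/tetraploid comparisons "matched" by construction.
`simulate_counts` draws per-bin counts NB with mean ∝ state·width·GC-bias
rescaled to the target read total, NB size = dispersion·state (matching the
fitted emission family; `dispersion=inf` gives Poisson), and exact zeros in
state-0 bins.

Defaults are the study conditions: a ~2.6 Gb genome in ~2,600 1 Mb bins
(20 chromosomes with linearly decreasing lengths), 40 cells, 130,000 reads
per cell (~50 reads per disomic bin), q = 0.1, NB size 20 at one copy
(variance/mean ≈ 2.3 at 50 reads — realistic scWGS overdispersion), no GC
bias (bias curves are available and exercised by the GC-correction tests).
Each cell owns a counter-derived RNG stream, so cohorts are bit-exactly
reproducible and order-independent.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: mappability structure (simulated grids are
near-uniform), sub-bin breakpoints, replication-timing and copy-neutral
artefacts, doublets, cross-contamination, or the heavy-tailed library
failures of real plates (the QC fixtures approximate degradation with
multiplicative lognormal noise and reduced depth). Real-data performance
is bounded by how well the NB family and the whole-chromosome event model
describe a given sample.

## Scaling of test and acceptance workloads

Recovery-style checks run at the full default scenario (20 cohorts × 40
cells × 2,600 bins) because the compiled forward-backward makes that
cheap; tests that only need a qualitative property (pipeline smoke runs,
subclone clustering, forced-ploidy comparisons) use 5–10-chromosome
genomes of 200–1,000 bins, which preserve every contract being tested at
a fraction of the cost. The acceptance script reports the problem size
used alongside every number.

## Known limitations

* No breakpoint refinement below bin resolution and no allele-specific or
  LOH calling; coverage at this depth cannot sample alternative alleles.
* The NB parameter tying (r_c = c·r₁, shared p) is a modelling decision;
  implementations that fit per-state parameters will differ in emission
  tails, most visibly at high copy numbers.
* The QC composite ("best mean rank") and the exact score formulas are
  this package's definitions of concepts that are often stated only in
  prose; scores are comparable across runs of this package, and the
  absolute H/D values should not be compared against other tools without
  checking their definitions.
* Separating G2 from near-tetraploid cells beyond the odd-modal-state rule
  is explicitly not attempted.
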