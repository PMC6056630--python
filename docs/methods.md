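# Methods

## Overview

`somportrait` implements an unsupervised portrayal analysis for bulk
transcriptomes.  The pipeline is: quantile normalization → gene-wise mean
centering → batch SOM of metagenes → per-sample portraits → variance-map
spot segmentation → gene-set scoring (Fisher enrichment, GSZ, population
maps) → correlation-silhouette class discovery → survival prognostics.
Every stage is deterministic given its seed.

## Preprocessing

Quantile normalization forces every sample column onto the common
distribution of per-rank means.  Ties within a column receive the mean of
the rank means their tie group spans, so tied inputs stay tied on output.
Centering subtracts each gene's mean over *all* samples (controls
included): portraits are therefore deviations from the cohort-wide average
transcriptome, which is what makes opposite ends of a severity axis appear
as anti-correlated portraits.  Median-centering and control-referenced
centering are plausible alternatives; mean-over-all was chosen because the
class-discovery machinery assumes portraits sum roughly to zero over the
cohort, and because it requires no labeled reference group.

## Metagene SOM

Genes are data points in sample space.  The codebook `C` (one row per grid
node, one column per sample) is trained by *batch* SOM: each epoch assigns
every gene to its nearest codebook row (Euclidean distance), then replaces
every row by the neighborhood-weighted mean of the gene profiles.
Parameters:

| parameter | default | meaning |
|---|---|---|
| `grid` | (50, 50) | map dimensions; 2500 metagenes at full scale, 20×20 for the desk-scale study conditions |
| `epochs` | 30 | batch epochs; the map is stable well before this at the sizes used |
| `radius_final` | 0.5 | Gaussian neighborhood SD at the last epoch; the radius decays linearly from `max(rows, cols)/2` |
| `seed` | 0 | only used for a degenerate-data fallback; initialization is otherwise deterministic |

Initialization is linear along the first two principal directions of the
gene cloud (SVD with a deterministic sign convention), which makes batch
training fully reproducible without an RNG.  Empty nodes keep their
previous codebook vector.  Plain nearest-codebook assignment is used (the
standard batch SOM); the full-epoch energy is then not guaranteed monotone
— only the codebook-update half-step is, and that is the property the test
suite asserts.  The weighted-BMU variant that restores full monotonicity
costs O(genes · nodes²) per epoch and is impractical at 50×50.

The variance map is the per-metagene unbiased variance (ddof = 1) of
codebook values across samples.  The U-matrix is the mean Euclidean
distance between a node's codebook vector and its 8-neighbors'.

## Spot segmentation

Pixels with variance strictly above a percentile of the variance map
(default 90) form the candidate region; 8-connected components become
spots; spot genes are the genes whose BMU lies inside.  Labels are letters
in descending total spot variance — they are stable identities within a
run, not positions.

With `split_umap=True`, each component is further partitioned by a
marker-based watershed of the U-matrix: markers are h-maxima of the
variance map *on the log scale* (`umap_h_rel = 0.25`, i.e. a peak must
stand a fixed factor above its surrounding dip — modules legitimately
differ in variance by orders of magnitude, so absolute prominence would
drop weak modules), and basins are grown along the U-matrix so borders
coincide with ridges of large neighboring-codebook distance.  Splitting is
off by default; it matters when distinct co-expression modules are
map-adjacent, as happens in the synthetic data where planted modules are
mutually orthogonal.

The default variance percentile (90) presumes that a small fraction of the
transcriptome is variant, as on real arrays.  The synthetic defaults plant
48% of genes in modules, so the recovery protocol derives its percentile
from the planted fraction, `100·(1 − 1.15·fraction)` clipped to [50, 90]
(= 55 at the defaults) — a data-driven choice, not a tuning constant.

A spot is *active* in a sample iff the mean portrait value over its pixels
strictly exceeds the q-quantile of that portrait and is positive.  The
default q = 0.98 corresponds to a ~50-pixel cut on a 50×50 map; on smaller
maps the protocol holds the cut at ~50 pixels (`q = 1 − 50/n_pixels`)
rather than at 2%, because a 2% cut on a 400-pixel map can fall *inside*
the dominant spot and deactivate everything.

## Gene-set scoring

Fisher spot enrichment is the one-sided (enrichment) exact test on the
in/out-of-spot × in/out-of-set table over the analysis universe;
Benjamini–Hochberg q-values are reported per spot across sets alongside
raw p-values, and pairs below 10⁻⁷ are flagged.

The per-sample gene set Z-score for set `G` (g of N genes) is

    GSZ_j = (mean_G e_gj − mean_all e_·j) / (s_j · sqrt((N − g) / (g (N − 1))))

the exact standardization of a g-element mean drawn without replacement
from sample j's transcriptome (s_j = per-sample SD across genes,
ddof = 1).  An optional `mode="shrunk"` stabilizes s_j toward the median
sample SD (`s² ← (1−λ)s² + λ·median(s)²`, λ = 0.1) for small or noisy
cohorts.  Set members absent from the matrix are dropped with a warning,
never imputed.  The named score table binds *severity* to the mean
expression profile of a designated spot (gene means, not metagene means)
and every other score (viral/IFN, erythrocyte, platelet, coagulation, …)
to the GSZ profile of a bound gene set.

## Class discovery

Samples are compared by Pearson correlation of their portrait vectors.
Labels are seeded by k-means (K default 6) on the rows of that correlation
matrix — hand-rolled deterministic Lloyd iterations with furthest-first
seeding and 20 restarts keeping the best inertia — then refined by
maximizing the correlation silhouette

    S_i = r(i, own centroid) − max_{c ≠ own} r(i, centroid_c)

where centroids are class-mean portraits (medoids were considered; means
match the averaging used for group portraits).  Each refinement iteration
moves all negative-S samples to their best class at once; a batch that
would lower the mean S is retried as a single worst-sample move and, if
that also lowers it, rolled back, terminating the loop — this makes the
mean-S trace non-decreasing by construction and guarantees termination
(cap 100 iterations).  Emptied classes restart on the worst-fitting
sample (logged).

Bootstrap stability (B default 100) redraws samples with replacement,
re-runs discovery, matches replicate to reference classes one-to-one by
greedy maximal centroid correlation, and reports the mean percentage of
in-bag samples keeping their label.  Correlation networks connect samples
by `r ≥ threshold` or mutual-union k-NN.

## Survival prognostics

The prognostic map computes, per metagene, the survivor percentage among
outcome-bearing samples whose portrait value exceeds `sd_factor` (default
1) times that metagene's SD across outcome-bearing samples.  The
exceedance is one-sided (over-expression); controls carry no outcome and
are excluded, including from the SD.  Metagenes supported by fewer than
`ceil(0.10 · N_outcome)` samples, or with zero SD, are masked (serialized
NA, rendered white).  Per-class survival tables report the survivor
percentage and a one-sided Fisher exact test of class vs rest, oriented
along the class's observed deviation.

## Synthetic data generator

The generator emulates a two-cohort pneumonia/sepsis blood study: 10
controls plus 170 patient samples (some patients sampled at days 1/3/5),
2000 genes, and expression

    e_gj = μ_g + Σ_k L_gk f_kj + ε_gj,   μ_g ~ N(8, 1),  ε ~ N(0, 0.4)

on a log-intensity scale.  Twelve disjoint 80-gene modules load on one
factor each (uniform 0.7–1.3 loading jitter):

| module | factor | default β |
|---|---|---|
| `sev_up` | severity u | 3.0 |
| `sev_dn` | −u | 3.0 |
| `sev_mid` | (4u(1−u))² — peaks at mid severity | 1.8 |
| `ifn` | IFN response v | 4.0 |
| `bd` | blood disturbance w | 4.0 |
| 7 decoys | independent z ~ N(0, σ_d(u)²) | 2.0 |

Latents: controls have u = 0.  Patients draw a severity tier (low / mid /
high, or IFN-low / IFN-high for IFN-active patients) and then u from a
Beta(2, 2) within the tier's band; the bands leave gaps around the
recorded class thresholds.  The IFN gate fires with cohort-specific
prevalence (0.40 in cohort D, 0.15 in cohort V), and v is a truncated
lognormal with a clear floor, so the IFN response is either absent or
unambiguous — the bimodal IFN-high/low stratification seen in real
cohorts.  Blood disturbance activates only at mid severity (probability
0.5), putting the erythrocyte/platelet signal at its empirically observed
mid-severity peak.  Decoy factor SD grows with severity
(σ_d = 0.15·(1 + u)), emulating the observation that variability from
independent transcriptional programs gains along the severity axis — this
is what makes active-spot counts rise from controls to severe cases.
Follow-up samples decay severity geometrically (δ = 0.8 per day beyond
day 1) and are snapped out of the threshold gaps so their labels stay
well-defined.

28-day death is Bernoulli with
`P = logistic(−2.6 + 2.2·u + 2.5·u·v)` from day-1 latents, which yields
expected class survivor rates of roughly 90% (low severity) down to ~55%
(IFN-high-severity) — the interaction plants the worst prognosis in the
IFN × high-severity corner.

The per-class label is a deterministic threshold function of (u, v, w)
recorded in the truth object.  Planted gene-set signatures are random 50%
subsets of each module, with size-matched decoy sets drawn from non-module
genes.

**What the generator does not emulate** — and hence what passing recovery
tests do not establish about real data: real severity is a continuum with
no density gaps, so label-exact class recovery (ARI) is only meaningful
here because the generator plants separable classes; real modules overlap,
correlate, and have heavy-tailed loadings; there are no probe effects,
batch effects, missing values, or technical replicates; noise is i.i.d.
Gaussian; and the module effect sizes are free parameters set (once, from
a pilot sweep) so that the planted structure is recoverable at the
documented thresholds, since no empirical effect sizes exist for these
axes.

## Numerical choices

- Quantile-normalization ties: mean of the spanned rank means.
- Variance denominators: ddof = 1 everywhere.
- Segmentation threshold: strictly above the percentile value, so a flat
  background tied at the threshold never floods the map.
- GSZ with |G| = N, or a zero-SD sample: score 0 by convention.
- Silhouette ties in "best class": lowest class index.
- Fisher tests use `scipy.stats.fisher_exact`; BH correction uses
  statsmodels.
- TSV output uses `%.17g` and round-trip float parsing, making re-runs
  byte-identical.
- Grid coordinates are 0-based and row-major in every output.

## Known limitations

- Spot labels (A, B, …) are rank identities; they do not correspond
  across runs or datasets.
- Batch SOM at 50×50 with >20k genes is the slowest stage (minutes, one
  CPU); the neighborhood matrix is O(nodes²) memory.
- The watershed split rule is a declared stand-in for an unpublished
  reference segmentation; its `umap_h_rel` prominence is heuristic.
- Bootstrap stability matches classes greedily; with many near-duplicate
  centroids an optimal assignment (Hungarian) could differ slightly.
- The desk-scale study conditions (2000 genes, 20×20 map, ten replicate
  seeds) are the package's default test bed; all thresholds quoted in the
  test suite refer to that scale.
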