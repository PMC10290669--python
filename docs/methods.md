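# Methods

This note documents the statistical models behind `gsinv`, the conventions
the implementation fixes where the underlying definitions leave room, the
synthetic data regimes used for validation, and known limitations.

## Pairwise sample statistics

All four statistics compare two samples across a common gene set and are
averaged over sample-pair groups (normal–normal, tumor–tumor,
normal×tumor). Conventions:

- **Pearson r** is the ordinary product-moment correlation; a constant
  vector yields NaN with a warning rather than an exception, so group
  averages over degenerate pairs surface visibly.
- **Spearman ρ** is computed as Pearson on midranks everywhere. The
  classical rank-difference formula assumes no ties; Pearson-on-midranks
  reduces to it in the tie-free case and remains well defined with ties.
- **Noise η²** of a gene across a sample pair uses the population
  (divide-by-n) variance, so η²ᵢ = (xᵢ−yᵢ)²/(xᵢ+yᵢ)² — the squared
  coefficient of variation. It is scale invariant: multiplying the matrix
  by any c > 0 changes nothing. Genes at zero in both samples have no
  defined noise and are excluded with a logged count.
- **Mutual information** is the plugin estimate on rank-transformed
  values cut into k equal-count bins, k from Doane's rule on the pooled
  midranks (with the per-vector n in the log₂ n term; untied ranks have
  zero skewness, so Doane reduces to Sturges). No bias-correction term is
  subtracted; the plugin estimator therefore carries a positive bias of
  roughly (k−1)²/(2n) under independence (≈ 0.05 nats at n = 1000,
  k = 11), which the tests assert explicitly. Statistics are computed on
  the abundance scale as given; an optional log2(x+1) pre-transform flag
  exists for heavy-tailed proteomic abundances.

## Size-matched resampling null

The null for a focal set of size s is built by drawing s genes uniformly
without replacement from the (post-filtering) matrix universe, n_reps = 100
times by default, and evaluating the statistic on each draw. The universe
is sorted before drawing so results depend only on seed and universe
contents, never on input order; focal genes stay inside the universe by
default (exclusion is a flag). The focal percentile uses the midrank
convention (#below + ½·#equal)/n_reps, which makes "invariance" a testable
statement: under exchangeability the percentile is uniform, verified by a
200-repetition Kolmogorov–Smirnov calibration check. When several
statistics are requested at once they are evaluated on one shared set of
draws, so their percentiles are comparable replicate by replicate and the
cost does not scale with the number of statistics.

## Distribution fitting and low-expression filtering

Each sample's positive abundances are fitted by maximum likelihood
(location fixed at zero) to log-normal, Pareto, Burr type XII,
log-logistic, and Weibull; log-normal and Pareto use their closed-form
MLEs, the Burr optimizer is seeded from the nested log-logistic fit. The
minimum-AIC family wins, with ties broken by fewer parameters, then a
fixed family order. Note that log-logistic is the d = 1 special case of
Burr XII and Weibull its d → ∞ boundary limit; when either generates the
data, plain AIC selects Burr whenever twice the likelihood gap exceeds 2,
which happens with probability ≈ P(χ²₁ > 2) ≈ 0.16 — an inherent property
of AIC among nested families, not an optimizer defect.

The low-expression filter makes a qualitative idea operational: per
sample, the threshold is the q-quantile (default q = 0.05) of that
sample's best-fitting distribution, and a gene is retained if its raw
value exceeds the threshold in at least half the samples. Zeros are
excluded from fitting but genes are filtered on raw values. The rule is
monotone in q. Fitting is per sample; no attempt is made to reproduce any
dataset-specific retained-gene count.

## Embeddings, trees, clustering

PCA treats samples as observations and genes as centered features (no
unit-variance scaling), on log2(x+1) values by default; between-condition
separation is the mean Euclidean distance over all normal×tumor pairs in
the 2-D score plane (full-gene-space distances are available as an
option). Neighbor joining is the classical Q-matrix algorithm from a star
topology, exact on additive matrices (the hard correctness test). Leaves
are processed in sorted-ID order and Q ties break on the lowest index
pair, making output platform-deterministic. Negative branch-length
estimates are clamped to zero with the deficit moved to the sibling edge;
raw estimates are kept in a diagnostic field. Hierarchical clustering uses
average linkage on the same distance matrix, and separation is scored as
the adjusted Rand index of the 2-cluster cut (for trees: the partition
from removing the longest internal edge) against condition labels;
single-condition inputs return NaN.

## Network analytics

Degrees are always taken from the full graph and restricted to set members
present in it; genes absent from the graph are excluded from the mean
(reported separately), matching "interactions per gene" semantics. The
degree-distribution exponent is the discrete maximum-likelihood estimate
for the tail k ≥ xmin with xmin fixed at 1 by default (configurable), and
is verified against a brute-force likelihood grid. Induced-subgraph
connectivity is reported as both the number of connected components and
the largest-component fraction; the latter carries directional claims,
since "more components" cannot coherently mean "better connected". The
mean-degree resampling null shares the bulk module's percentile machinery.
On heavy-tailed graphs the null's upper percentiles are volatile: a single
mega-hub entering a handful of the 100 random sets can shift the 97.5th
percentile substantially, so detection of a planted degree boost has a
per-seed success probability near, not at, one (≈ 0.93 measured at the
synthetic study conditions).

## Single-cell stage

Cells pass QC with more than 200 detected genes and mitochondrial fraction
below 0.15; counts are normalized per cell as ln(1 + count/total × 10⁴).
Within each cluster present in both conditions (≥ 3 cells each), genes
detected in at least 50% of cells of *either* condition group — the
permissive reading of the detection filter — are tested by two-sided
Wilcoxon rank-sum on normalized values, with Benjamini–Hochberg adjustment
within the cluster (unadjusted Wilcoxon at single-cell n is
anti-conservative). log-fold-change is reported as the difference of
ln(1 + mean normalized expression) between groups. Cluster labels are
taken as given; clustering itself is out of scope. The focal fraction is
|significant ∩ focal| / |significant|, per cluster and for the union of
significant genes overall.

## Synthetic data: what it emulates, and what it does not

- **Bulk** (defaults: 2000 genes, 5+5 samples, focal 100): per-gene
  log-normal baseline means (meanlog 2.0, sdlog 1.5, spanning several
  orders of magnitude like TPM), multiplied by unit-mean log-normal noise
  with condition-specific CV — 0.3 for normal, 0.6 for tumor, encoding the
  observation that tumor replicates are noisier. Focal modes: `invariant`
  (focal genes exchangeable with the rest — the null hypothesis the
  pipeline must *not* reject), `divergent` (tumor means of focal genes
  scaled by a fold change), `low_noise` (focal CVs divided by the effect).
  Five replicates per condition reflects small patient cohorts.
- **Network** (defaults: 2000 nodes, α 2.5, focal 100): a discrete
  power-law target degree sequence realized by the configuration model
  with self-loops and collapsed multi-edges discarded; an odd stub total
  is repaired by one logged extra stub. Focal target degrees can be
  multiplied by a boost factor, and extra within-focal edges can be
  planted to make the focal induced subgraph preferentially
  interconnected. Configuration-model realization (rather than
  preferential attachment) keeps the exponent directly plantable.
- **Single cell** (defaults: 1000 genes, 3 clusters, 100 cells per cluster
  per condition): negative-binomial counts via a gamma–Poisson mixture
  (dispersion 2, mean ≈ 2 so most genes pass the 50% detection filter),
  mild per-cluster expression modulation, uniform per-cell mitochondrial
  fractions. Per cluster, round(de_fraction·n_genes) genes receive a
  tumor shift of ±de_logfc with exactly round(focal_overlap·n_de) of them
  from the focal set — the planted focal share is a construction identity.
  Planted effects are **mass-balanced**: the up-regulation probability is
  chosen so the planted genes' total expected expression is conserved (and
  then rescaled exactly), because unbalanced effects shift library sizes
  and per-cell normalization would turn every unplanted gene into a
  compositional false positive. Real tumors are not guaranteed to be
  composition-neutral; passing these tests shows the DE machinery recovers
  per-gene signal, not that normalization artifacts cannot occur in real
  data.

The generators model none of: batch effects, doublets, ambient RNA,
informative proteomic missingness (missing-completely-at-random only),
gene–gene correlation structure, or tumor purity. Recovery results
therefore validate the statistical machinery, not robustness to those
artifacts.

## Determinism and problem sizes

Every generator and resampler takes an explicit seed; the orchestrated run
expands one global seed into fixed per-stage substreams (a stable spawn
key per stage), so adding a stage never perturbs earlier stages' draws and
reruns are byte-identical. Monte-Carlo validation uses 20 seeds per
experiment at the study conditions above, with 100-draw nulls and a
200-repetition calibration check — sizes chosen so each recovery
experiment carries clear statistical power while the whole suite runs in
minutes on one CPU.

## Known limitations

- Gene identifiers are opaque, case-sensitive strings; no symbol/alias or
  cross-database harmonization is attempted.
- The MI estimator is the plain plugin form; its positive bias is
  documented, not corrected (a correction flag exists for the entropy
  estimate's future extension, defaulting off).
- Power-law fitting fixes xmin rather than optimizing it; for empirical
  degree sequences whose head deviates from the power law, the exponent
  is a whole-distribution summary, not a tail estimate.
- The 2-cluster separation score of an unrooted tree depends on the
  longest-internal-edge cut, which can be unstable when two internal
  edges have near-equal lengths.
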