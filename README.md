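# gsinv — gene-set invariance analysis

Curated oncogene panels are expected to behave differently from arbitrary
genes, yet in bulk tumor/normal expression data they often do not: their
pairwise sample statistics are statistically indistinguishable from those of
random gene sets of the same size, while their protein–protein interaction
connectivity and per-cluster single-cell differential expression are not.
`gsinv` packages this "invariance analysis" as a tested, reusable pipeline
for anyone who wants to ask, of *any* focal gene set: **does this set carry
signal beyond its size?**

## What it computes

For two samples X, Y over a common set of *n* genes:

- **Pearson correlation** r(X, Y) and **Spearman correlation** ρ(X, Y)
  (Pearson on midranks).
- **Mutual information** MI(X, Y) in nats: each sample is rank-transformed,
  ranks are cut into *k* equal-count bins with *k* from Doane's rule
  (k = ⌈1 + log₂n + log₂(1 + |g₁|/σ_g₁)⌉), and the plugin estimate
  Σ p(x,y) ln[p(x,y)/(p(x)p(y))] is returned.
- **Expression noise** η²ᵗᵒᵗ = (1/n) Σᵢ σ²ᵢ/μ²ᵢ, the mean squared
  coefficient of variation per gene across the sample pair.

Each statistic is averaged over sample-pair groups — normal-vs-normal,
tumor-vs-tumor, and normal-vs-tumor cross pairs — and the focal set's value
is located inside a **size-matched resampling null**: the distribution of
the same statistic over (by default) 100 uniform random gene sets of equal
size. A central empirical percentile means the focal set is "invariant";
an extreme one means it carries signal beyond its size.

Around this core the package provides per-sample distribution fitting
(log-normal / Pareto / Burr XII / log-logistic / Weibull, minimum-AIC
selection) with fitted-tail low-expression filtering; PCA sample embeddings
with between-condition Euclidean distances; classical neighbor-joining
sample trees (exact on additive distances) and average-linkage clustering
with an adjusted-Rand separation score; interaction-network degree
analytics (discrete power-law MLE, per-set mean degree with a resampling
null, induced-subgraph connectivity); and a single-cell stage (QC,
LogNormalize, per-cluster Wilcoxon DE with Benjamini–Hochberg adjustment,
focal fraction of DE genes). A synthetic-data module generates bulk
matrices, scale-free networks, and clustered negative-binomial counts with
planted, recoverable structure, so the whole pipeline is testable without
external data.

## Worked example

```python
from gsinv import synthio, resample, pairstats

m, focal = synthio.simulate_bulk(synthio.BulkSimConfig(seed=1))
rep = pairstats.aggregate_pairs(m, "NvsT", subset=focal)
print(f"focal set, N-vs-T over {rep.n_pairs} sample pairs: "
      f"r={rep.r:.3f} rho={rep.rho:.3f} MI={rep.mi:.3f} eta2={rep.eta2:.3f}")

nulls = resample.build_nulls(m, focal, ["r:NvsT", "eta2:NvsT"],
                             n_reps=100, seed=2)
for name, null in nulls.items():
    print(f"{name}: focal={null.focal_value:.3f} "
          f"null mean={null.values.mean():.3f} percentile={null.percentile:.2f}")
```

prints

```
focal set, N-vs-T over 25 sample pairs: r=0.852 rho=0.887 MI=0.838 eta2=0.081
r:NvsT: focal=0.852 null mean=0.852 percentile=0.49
eta2:NvsT: focal=0.081 null mean=0.084 percentile=0.26
```

The simulated focal set was planted as exchangeable with the rest of the
genes, and the null agrees: its cross-condition correlation and noise sit
squarely inside the random-set distribution (percentiles 0.49 and 0.26) —
the invariance signature. Re-running with
`BulkSimConfig(focal_mode="divergent", focal_effect=4.0)` plants a fourfold
tumor shift on the focal genes and pushes the noise percentile to 1.0.

The same analysis runs from the shell, end to end, from one YAML config:

```bash
gsinv synth bulk --out data/ --seed 3          # or bring your own TSV/GMT
gsinv run --config run.yaml --out results_dir/
```

Subcommands `distfit`, `pairstats`, `resample`, `simreduce`, `network`, and
`scdeg` expose the individual stages for file-based inputs.

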