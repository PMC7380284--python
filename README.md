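# evotiss

Multi-tissue transcriptome features and the **tissue-anchored model** of
protein sequence evolution.

The rate of protein sequence evolution, measured as ω = dN/dS (the ratio
of nonsynonymous to synonymous substitution rates between orthologs), is
strongly coupled to how a gene is expressed: highly and broadly
expressed genes evolve slowly. `evotiss` is a toolkit for studying these
couplings in a multi-tissue RNA-seq framework, built for analysts who
work with gene-by-sample expression matrices (GTEx-style RPKM tables),
per-gene substitution rates, protein-interaction networks and gene-level
clinical annotations. Because such resources cannot ship with a package,
a first-class synthetic generator reproduces their statistical structure
so that every stage is testable end to end.

## What it computes

* **Per-tissue expression features** — mean, median, variance and
  variance-to-mean of expression per gene and tissue (raw or log2(x+1)
  scale), and the expression-breadth statistic
  τ = Σᵢ (1 − x̂ᵢ)/(n − 1), x̂ᵢ = xᵢ / maxⱼ xⱼ,
  which is 0 for uniform expression and 1 for single-tissue expression.
* **The tissue-anchored model** — each gene's *MaxTissue* is the tissue
  where it attains its maximum inter-individual expression variance
  (*MaxVariance*). Association of MaxTissue with ω is tested by a
  Kruskal–Wallis H (tie-corrected), backed by a gene-count-preserving
  permutation null, and summarized per tissue by the median ω of its
  anchored genes with the dispersion metric
  δ = 3.14 (v₇₅ − v₂₅)/√n. An overlap test (chi-square plus a
  Mantel–Haenszel matched odds ratio) checks whether MaxTissue predicts
  the primary affected organ of developmental disorders.
* **EPRCA** — empirical partial rank correlation: the first-order partial
  Spearman r_{DK|X′} with a permutation null obtained by shuffling
  (D, X′) jointly (preserving their correlation exactly), an empirical p
  and the adjusted coefficient θ̂ = √(max(r² − E(M₀)², 0)).
* **GLS under co-expression** — π̂ = (dNᵀΔ⁻¹dN)⁻¹dNᵀΔ⁻¹G with
  var(π̂) = (dNᵀΔ⁻¹dN)⁻¹σ̂², solved by Cholesky factorization of the
  known co-expression covariance Δ.
* **Permutation nulls** — branch-(gene-age-)preserving shuffles of ω and
  degree-preserving network nulls (exact double-edge-swap rewiring, or
  attribute shuffles within log₂ degree strata).
* **Boosted joint model** — gradient-boosted regression trees (squared
  error, shrinkage 0.01, interaction depths 1/4/5, 100–10000 trees) of
  log ω on the feature set, with a normalized feature-importance
  spectrum and out-of-sample adjusted R² over 70/30 splits.
* **TWAS power** — per-gene power of a transcriptome-wide association
  test from the non-central chi-square(1, λ) tail with
  λ = N·R²·φ², comparing conserved (ω < 0.01) against fast-evolving
  (ω > 1) genes.

## Worked example

```python
import numpy as np
from evotiss import SimConfig, simulate_dataset, build_feature_table
from evotiss.anchor import anchor_test
from evotiss.model import BoostConfig, fit_boosted, out_of_sample_r2
from evotiss.pipeline import boost_design

data = simulate_dataset(SimConfig(n_genes=5000, seed=1))
ft = build_feature_table(
    data.expression, rates=data.rates, network=data.network,
    branches=data.branches, imputation_r2=data.imputation_r2, scale="log2p1",
)
print("tau median:", round(ft.summary["tau"].median(), 3))

res = anchor_test(ft.summary["max_tissue"].to_numpy(),
                  data.rates.omega.to_numpy(), n_perm=1000, seed=2)
print(f"Kruskal-Wallis H = {res.h_statistic:.1f}, "
      f"analytic p = {res.p_analytic:.2e}, "
      f"permutation p = {res.permutation.empirical_p:.3f}")

X, y = boost_design(ft, data.rates)
model = fit_boosted(X, y, BoostConfig(n_trees=1000, interaction_depth=4, seed=5))
print(model.feature_importances_.sort_values(ascending=False).head(3))
r2 = out_of_sample_r2(X, y, BoostConfig(n_trees=1000, interaction_depth=4,
                                        seed=5), n_splits=10)
print("mean out-of-sample adjusted R^2:", round(float(np.mean(r2)), 3))
```

prints

```
tau median: 0.829
Kruskal-Wallis H = 78.7, analytic p = 7.18e-04, permutation p = 0.001
max_variance    62.3
tau             11.5
mean_level      10.4
Name: importance, dtype: float64
mean out-of-sample adjusted R^2: 0.518
```

Read it as: the synthetic catalog shows the expected heavily
tissue-specific τ spectrum (median 0.83); the tissue in which a gene's
expression varies most carries significant information about its
evolutionary rate (the permutation p is at the resolution of the 1000
label shuffles); MaxVariance dominates the importance spectrum of the
joint model, which explains about half of the variance in log ω out of
sample — consistent with the 60% of log-ω variance the generator assigns
to its feature-driven signal (the anchor-tissue shifts and measurement
noise account for the remainder).

The same analysis is scriptable from the shell:

```sh
evotiss simulate --out-dir run --seed 1
evotiss features --expression run/expression.tsv --tissue-map run/tissue_map.tsv \
    --rates run/rates.tsv --out run/features.tsv --scale log2p1
evotiss anchor --features run/features.tsv --rates run/rates.tsv \
    --out-prefix run/anchor --n-perm 1000 --seed 2
# or the whole chain with one config:
evotiss run --config cfg.yaml --out-dir run --seed 1
```

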