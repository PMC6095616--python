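# dyncorr — Dynamic Correlation Analysis

`dyncorr` finds latent factors that govern *changing* correlations in a
gene × sample expression matrix.  Many gene pairs do not have a fixed
correlation: their correlation strengthens, weakens, or flips sign as an
unobserved cellular state `Z` varies across samples
(`cor(g_i, g_j) = f(Z)` with `f` monotone).  Classic dimension-reduction
methods (PCA, ICA, kernel PCA) look for patterns in the *means* of genes
and miss this second-order structure entirely; triplet-screening
approaches ("liquid association") use individual genes as surrogates of
`Z`, which is both O(p³) and unreliable.  `dyncorr` recovers the shared
latent signals directly, for bulk or single-cell expression data.

## Method

All genes are standardized to mean 0, sd 1 (population divisor, so
`g_i·g_j / N = r(g_i, g_j)`).

1. **Screening — the Liquid Association Coefficient (LAC).**  For every
   pair, either
   `ζ = r(g_i², g_j²) − r²(g_i, g_j)` (squared form) or
   `ζ = r(|g_i|, |g_j|) − |r(g_i, g_j)|` (absolute form, default).
   For a bivariate-normal pair the squared form converges to zero at
   any fixed correlation, while a pair whose correlation varies across
   samples scores positive — so ranking by ζ surfaces candidate
   dynamically correlated pairs without knowing `Z`.  The top 2.5% of
   pairs (capped at 10⁶) are kept.

2. **Dynamic Components.**  Each selected pair contributes a row
   `h = (g_{i,1}g_{j,1}, …, g_{i,N}g_{j,N})` to the matrix **H**.  When
   `Z` is standard normal, `z·h / N` estimates the expected derivative
   of the pair's conditional correlation with respect to `Z`, so
   latent factors are the unit vectors

   `z₁ = argmax_{‖z‖=1} Σ_m (z·h_m)²,  z_k ⊥ z_1..z_{k−1}`,

   i.e. the top eigenvectors of the N×N matrix **H′H** — the *Dynamic
   Components* (DCs).  An optional varimax rotation aligns the leading
   components with distinct groups of pairs.

3. **Pair association via lfdr.**  For each DC, the statistic
   `γ_m = z·h_m` is computed over a broad candidate pool (top 20% of
   pairs by ζ).  Most pool pairs are unrelated to `z`, so the γ
   collection follows a two-group mixture
   `f(γ) = π₀f₀(γ) + (1−π₀)f₁(γ)`; each pair gets a local false
   discovery rate `lfdr = π₀f₀(γ)/f(γ)` (empirical-null central
   matching, spline-smoothed marginal), and pairs with lfdr ≤ 0.01 are
   called associated, signed by γ.

4. **Enrichment.**  Called pairs are summarized against a gene-set
   collection (GMT): within-set and between-set (overlap removed) pair
   counts vs a random-draw binomial null, with fold change and
   one-sided p-value, exported as a process-pair network (GraphML).

A simulation module generates datasets with known latent structure
(three conditional-correlation designs, optional quantile matching to
skewed zero-inflated marginals) and an evaluation module scores factor
recovery, so the full pipeline is testable offline.

## Worked example

```python
import numpy as np
from dyncorr import (SimulationSpec, simulate_dataset, standardize,
                     lac_matrix, select_top_pairs, build_h, extract_dcs,
                     match_factors, pca_baseline)

spec = SimulationSpec(n_modules=3, genes_per_module=100, n_samples=500,
                      noise_sd=0.5, setup="s1", seed=7)
ds = simulate_dataset(spec)          # 300 module genes + 300 noise genes
X = standardize(ds.X)
table = lac_matrix(X, form="absolute")
top = select_top_pairs(table, top_frac=0.025, max_pairs=1_000_000)
H = build_h(X, top)
dcs = extract_dcs(H, K=5)            # K + 2 factors for 3 true modules
rec = match_factors(ds.true_factors, dcs.scores)
pca = match_factors(ds.true_factors, pca_baseline(X, 5))
print(f"genes: {X.n_genes}, pairs scored: {table.n_pairs}, selected: {len(top)}")
print(f"top eigenvalues: {np.round(dcs.eigenvalues, 1)}")
print(f"DCA  mean |Spearman| with truth: {rec.mean_abs_cor:.3f}")
print(f"PCA  mean |Spearman| with truth: {pca.mean_abs_cor:.3f}")
```

Output:

```
genes: 600, pairs scored: 179700, selected: 4493
top eigenvalues: [63244.5 58040.6 47552.5 36444.7 30004. ]
DCA  mean |Spearman| with truth: 0.697
PCA  mean |Spearman| with truth: 0.066
```

The three latent factors drive only the *correlations* among module
genes, never their means — so PCA sees nothing (0.066, chance level)
while the Dynamic Components track the hidden factors (0.697; the
generator's ten seed pairs per module bound what any method can reach —
see `docs/methods.md`).

The same pipeline is available from the shell:

```sh
dca simulate --setup s1 --modules 3 --genes-per-module 100 \
    --samples 500 --seed 7 --out sim/
dca run --input sim/matrix.tsv --k 5 --out-prefix results/run1
dca evaluate --true sim/factors.tsv --found results/run1/dc_scores.tsv \
    --out eval.tsv
```

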