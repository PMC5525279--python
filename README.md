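# matcher

Manifold alignment of single-cell multi-omic data: infer a shared "master
time" axis from transcriptomic and epigenomic measurements made on
*different* cells, and use a generative model to read one modality's
measurements off another's cells.

## The problem

Single-cell assays destroy the cell, so gene expression, chromatin
accessibility, histone marks and DNA methylation are usually profiled in
separate cell populations sampled from the same biological process
(differentiation, reprogramming, ...). Each modality supports its own
pseudotime ordering, but those orderings are not comparable: they differ in
orientation, in scale, and in "time warping" — different genomic quantities
change at different rates along the same process. This package aligns the
per-modality one-dimensional manifolds without any cell-to-cell
correspondence, so that epigenome and transcriptome dynamics can be
correlated at single-cell resolution.

## The model

For each modality the observed matrix **Y** (cells × features,
standardized) is modeled with a Bayesian Gaussian-process latent variable
model (GPLVM) with a single latent variable *t* per cell:

    Y = f(t) + ε,   f ~ GP(0, k),   ε ~ N(0, σ²I),
    k(tᵢ, tⱼ) = σ²_rbf · exp(−(tᵢ − tⱼ)² / (2l²))

The posterior over *t* is estimated by the collapsed variational
approximation with inducing inputs (10 by default), maximizing the evidence
lower bound over the per-cell variational moments, the inducing inputs and
the kernel hyperparameters (σ², σ²_rbf, l), starting from PCA.

The latent pseudotime is then oriented using prior knowledge (an explicit
rule or a marker feature with known direction), rescaled to [0, 1], and
warped onto **master time**: the sample quantiles of pseudotime are aligned
with the quantiles of a uniform(0, 1) variable, and the monotone warping
function is fitted by GP regression (with a linear-interpolation fallback
whenever the GP mean is not monotone; 50 quantiles by default). Master time
is uniform on [0, 1] by construction and directly comparable across
modalities.

Because the GPLVM is generative, a cell measured with one assay can be
mapped through its master time and the inverse warping of another modality
to a pseudotime there, and the second modality's GPLVM predicts the
measurement that cell *would* have produced. Downstream statistics built on
this: cross-modality Spearman/Pearson feature correlations, a decoupling
test comparing the coupling of two master times before/after a split point
(Fisher r-to-z plus a 100,000-draw permutation test), a shared GPLVM for
protocols that measure two modalities in the same physical cell, and
lagging-cell identification against experimental time points.

## Worked example

```python
import numpy as np
from scipy.stats import pearsonr

from matcher import MatcherModel, RunConfig, SimSpec, simulate_paired_modalities

# Two modalities generated from one shared biological process, measured on
# disjoint 50-cell subsets, with different time warps and noise at 25% of
# the feature range
rna_spec = SimSpec(seed=11, n_cells=100, n_features=600,
                   warp_family="identity", noise_sigma=4.0, modality_name="rna")
atac_spec = SimSpec(seed=12, n_cells=100, n_features=600,
                    warp_family="power:2", noise_sigma=4.0, modality_name="atac")
rna, atac, truth = simulate_paired_modalities(rna_spec, atac_spec,
                                              subsample=(0.5, 0.5), seed=10)

config = RunConfig(seed=10, orientation={
    "rna": "marker:rna_g0000:decreasing",   # prior knowledge of one marker
    "atac": "marker:atac_g0000:decreasing",  # direction per modality
})
results = MatcherModel([rna.Y, atac.Y], config).fit()
print(results.summary())
```

```
Manifold alignment results
  seed: 10  inducing inputs: 10  quantiles: 50
  [rna] cells=50 features=600 elbo=-31434.32 orientation=reverse warp=interp KS(master vs U[0,1])=0.020 lengthscale=1.33
  [atac] cells=50 features=600 elbo=-32900.15 orientation=keep warp=interp KS(master vs U[0,1])=0.020 lengthscale=1.47
```

Each modality gets its own GPLVM fit (ELBO, kernel lengthscale), an
orientation decision driven by the declared marker, and a warping; the
KS statistic near 0.02 confirms master time is uniform on [0, 1]. Since the
data are simulated, we can score the alignment against the generating truth
and correlate features across modalities through the generative model:

```python
acc_rna = abs(pearsonr(results.master_time("rna"), rna.true_master).statistic)
acc_atac = abs(pearsonr(results.master_time("atac"), atac.true_master).statistic)
print(f"master-time accuracy vs ground truth: rna {acc_rna:.3f}, atac {acc_atac:.3f}")

corr = results.cross_modality_correlation(
    "rna", "atac", ["rna_g0001", "rna_g0002"], ["atac_g0001", "atac_g0002"])
print(corr.round(3))
```

```
master-time accuracy vs ground truth: rna 0.998, atac 0.992

           atac_g0001  atac_g0002
feature_a
rna_g0001       0.063       0.719
rna_g0002      -0.193      -0.758
```

Both modalities recover the hidden process ordering (Pearson ≥ 0.99 against
the true master time), and the correlation matrix relates *observed* RNA
features to *generated* chromatin measurements for the same (RNA-assayed)
cells — e.g. `rna_g0001` and `atac_g0002` rise together along the process
(Spearman 0.72) even though no cell was measured with both assays.

The same pipeline is available from the shell:

```
matcher simulate --n-cells 100 --sigma 9 --seed 1 --out sim/
matcher fit --input sim/Y.tsv --out fit.json
matcher align --input rna=sim/Y.tsv --seed 1 --out aligned/
matcher decouple --model1 aligned/model_a.json --model2 aligned/model_b.json --out dec.json
```

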