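# slesa — spatially localized ensemble sparse analysis

`slesa` classifies fixed-length feature vectors — typically deep features
extracted from breast-mass ROIs by a convolutional network — as **benign**
or **malignant** using block-wise sparse representation classification.
It is aimed at computer-aided diagnosis (CADx) research where training
sets are small and an interpretable, training-free classifier over
pre-extracted features is preferable to end-to-end fine-tuning.

## Method

A length-`l` feature vector is cut into `np = ⌊l/s⌋` blocks of length
`s`. Training samples supply labeled dictionary atoms, in one of two
decompositions:

* **BlockBoost** — one dictionary per block index:
  `D_i = [d_1^i … d_k^i]` holds block `i` of all `k` training samples;
  block `i` of a test vector is coded only against `D_i`.
* **PatchSample** — one pooled dictionary
  `D = [d_1^1 … d_1^np, d_2^1, … d_k^np]` of all `k·np` training blocks;
  every test block is coded against it.

Each test block `y_j^i` gets an L1-minimal sparse code by basis pursuit
denoising in constrained form,

```
x̂_j^i = argmin ‖x‖₁   subject to   ‖y_j^i − D x‖₂ ≤ ε,
```

solved on the lasso penalty path (the path is piecewise linear, so the
penalty at which the residual meets ε is found in closed form). Keeping
only the coefficients of class-`c` atoms gives class-specific residuals
`r_m` (malignant) and `r_n` (benign), a per-block log-likelihood score

```
LLS(x̂_j^i) = −[log r_m(x̂_j^i) − log r_n(x̂_j^i)],
```

and the ensemble score `ELLS(x̂_j) = (1/np) Σᵢ LLS(x̂_j^i)`. The
prediction is `sgn(ELLS)`: positive → malignant, otherwise benign.

Also included: conventional SRC (no block decomposition, optional PCA),
label-specific dictionary learning via K-SVD (LS-SLESA / LS-SRC), a
stratified 10-fold cross-validation harness with ACC / TPR / TNR / AUC,
per-component Kullback–Leibler divergence diagnostics, decision-score
histograms, and a synthetic generator that plants class-specific sparse
structure with known ground truth.

## Worked example

```python
from slesa import SyntheticSpec, PipelineConfig, generate, cross_validate

spec = SyntheticSpec(n_per_class=50, l=128, atoms_per_class=8,
                     sparsity=2, noise_sigma=0.3, seed=42)
features, truth = generate(spec)

config = PipelineConfig(mode="blockboost", block_length=32, epsilon=0.05)
report = cross_validate(features, config, folds=10, seed=0)

print("pooled metrics (%):", report.as_percent())
print("confusion counts:", report.counts)
print(report.per_fold[["fold", "n", "acc", "auc"]].head(3).to_string(index=False))
```

prints

```
pooled metrics (%): {'ACC': 80.0, 'TPR': 82.0, 'TNR': 78.0, 'AUC': 88.2}
confusion counts: ConfusionCounts(TP=41, TN=39, FP=11, FN=9)
 fold  n  acc  auc
    0 10  0.9 0.96
    1 10  0.9 1.00
    2 10  0.8 0.92
```

100 samples of length 128 are drawn from two disjoint 8-atom latent
subspaces with noise σ = 0.3 (substantial: atoms are unit-norm).
BlockBoost with `s = 32` (4 blocks, ε = 0.05·‖y‖ per block) classifies
80% of held-out samples correctly; sensitivity to the malignant class is
82%, specificity 78%, and the continuous ensemble score separates the
classes with AUC 88.2%. At σ = 0.01 the same pipeline reaches 100%.

The same run from the shell:

```bash
slesa synth --spec spec.yaml --out features.csv
slesa cv --config run.yaml --out-dir results/
```

where `run.yaml` names the features file, mode, block length, ε, fold
count and seed. Other subcommands: `pool`, `pca`, `dict`, `ksvd`,
`classify`, `sweep` (see `slesa --help`).

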