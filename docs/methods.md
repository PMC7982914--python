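# Methods

## Model

`mkfuse` classifies tumor subtypes from several molecular profiles
("views") of the same patients. The modelling assumptions are those of
kernel fusion: (i) each view induces a meaningful pairwise similarity
between patients; (ii) subtype structure is a *shared* signal — the same
partition of patients — expressed with different strength per view;
(iii) a convex combination of the per-view Gram matrices is itself a valid
similarity on which a maximum-margin classifier can operate.

Pipeline per cross-validation fold:

1. optional feature z-scoring (train statistics only);
2. PCA to a small per-view dimension, fit on the training half
   (`fold_safe`) or once on all samples (`paper_mode`);
3. one kernel per view (Tanimoto, Pearson or cosine) over all samples;
4. fusion weights from the *training* sub-Gram and training labels;
5. convex combination, eigenvalue clipping to PSD, SVM on the training
   block, prediction of the held-out block.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `pca_dim` per view | presets: gene 40, meth 40, isoform 20 (3-class) / 30 (2-class) | components retained per view; the preset dimensions are typical working points for expression and methylation cohorts of this scale, and are overridable per config |
| kernel kind per view | presets: tanimoto/pearson/cosine (3-class), cosine/cosine/tanimoto (2-class) | per-view similarity; Pearson is the correlation of two *sample* vectors over the reduced coordinates, so all three produce n × n kernels |
| `mkl_method` | `hsic` | weighting rule; `fkl` solves the ridge QP, `mean` is the uniform baseline |
| `fkl_lambda` | 1.0 | ridge ("equilibrium") coefficient of the FKL QP; λ→∞ drives weights to uniform, λ=0 with duplicate kernels leaves the optimum non-unique (the solver's minimum found is accepted) |
| `ideal_encoding` | `onehot_FFt` | target matrix F Fᵀ from one-hot class indicators (valid for any class count); `signed_yyT` (±1 outer product) available for binary problems |
| SVM `C` | 1.0 | soft-margin constant; kernels are O(1)-scaled so 1.0 is a neutral default |
| `multiclass_scheme` | `one_vs_one` | the native SVM dual decomposition; one-vs-rest available |
| CV | stratified 2-fold, seed 0, 1 repeat | twofold is the evaluation protocol of record here; repeats pool predictions across reseeded fold draws |
| `psd_repair` | on | eigenvalue clipping of the *combined* kernel only; cosine/Pearson Grams are PSD by construction, Tanimoto on real vectors need not be |

Weight-from-score rule for HSIC/KTA: scores are clipped at zero and
L1-normalized — the simplest map onto the simplex constraint. All-zero
scores fall back to uniform weights.

## Numerical choices

- **FKL QP.** Solved by SLSQP with analytic gradient, objective scaled to
  O(1), multi-start (uniform + each simplex vertex), and a KKT residual
  check at 1e-6. Validated in the tests against brute-force enumeration of
  the simplex at grid step 1e-3 (J ≤ 3).
- **PCA determinism.** Full SVD; each component's sign is fixed so its
  largest-magnitude loading is positive.
- **Degenerate kernel rows.** Two zero vectors: Tanimoto 1 (identical);
  one zero: 0. Constant rows under Pearson: 0 off-diagonal, diagonal forced
  to 1. Nonpositive Tanimoto denominators clamp the similarity to 0.
- **Ties.** One-vs-one voting ties are resolved by the aggregate decision
  value, then lexicographic class order (scikit-learn's deterministic
  behaviour with `decision_function_shape="ovr"`).
- **Sample ordering.** After alignment, samples are sorted
  lexicographically by id, making fold assignment a pure function of
  (ids, labels, seed); reports are byte-reproducible.
- **Binary metric convention.** The positive class is the
  lexicographically second class label. Sensitivity is TP/(TP+FN),
  specificity TN/(TN+FP). For >2 classes: SN = micro-averaged recall
  (numerically equal to ACC), SP = macro one-vs-rest specificity,
  MCC = Gorodkin's multiclass form, AUC = macro one-vs-rest; zero
  denominators yield 0.

## Synthetic data: what it emulates and what it does not

The generator draws, per view, class means at exact pairwise distance
`separation · σ` inside a low-dimensional informative subspace (scaled
standard-basis vectors), adds isotropic Gaussian noise, and pads with
pure-noise ambient dimensions. Defaults: 60 samples per class, 3 views,
ambient dimension 500, informative dimension 10, σ = 1, separation 6 —
a deliberately scaled-down analogue of subtype cohorts (hundreds of
samples, tens of thousands of features) sized so the suite runs in
seconds. Sample ids can be synthesized as TCGA-style barcodes with a fake
project code, mixing in non-tumor type codes to exercise the barcode
filter.

What it captures: shared label structure across views, per-view
informativeness (the weighting methods must find the informative view),
high ambient dimension ahead of PCA, 2- and 3-class settings. What it does
not: the skewed marginals of RSEM counts or methylation beta values, batch
effects, missingness, or correlated noise between views. Passing tests
therefore demonstrate the machinery — fold hygiene, weight recovery,
separability when the signal is strong — not performance on real cohorts.

Note on difficulty: with fold-training size n = 90 and ambient dimension
p = 500, the largest pure-noise sample eigenvalues (Marchenko–Pastur edge
≈ (1+√(p/n))² σ²) exceed the class-structure eigenvalue (≈ 5 σ² at
separation 6), so retained principal components mix noise directions and
pooled accuracies sit near — not at — the noiseless ceiling. This is the
intended regime: an easier default would not discriminate between
weighting rules.

## Design choices

- Kernel weights are computed strictly from training-fold rows/columns of
  each kernel; the resulting β is applied to the full kernels. A `global`
  scope (weights from all samples) is available to reproduce
  non-fold-safe workflows, as is `paper_mode` PCA (fit once on all
  samples); both leak label/test information by construction and are off
  by default.
- Tanimoto is applied to real-valued PCA scores exactly as defined, not
  binarized.
- The ideal-kernel default is the one-hot form for all class counts; the
  signed ±1 form does not generalize past two classes.
- Missing cells are rejected by default; `impute_missing` substitutes
  feature-wise means.

## Known limitations

- Fusion weights are global per fold, not sample- or region-specific.
- No hyperparameter search: C, λ, and PCA dimensions are taken from the
  config.
- Kernel matrices are dense; memory is O(n²) per view, which is fine for
  cohort-scale n (≤ a few thousand) but not for biobank-scale inputs.
- The barcode filter implements exactly the 01–09 tumor-code rule; any
  additional cohort-specific deduplication must happen upstream.

## Problem sizes in the distributed checks

The test suite and `scripts/acceptance.py` use 60 samples per class
(n = 180 for three classes, 120 for two), ambient dimension 500 reduced to
10 PCs, twofold CV, and 20 generator seeds for the view-ranking study —
sizes chosen so a full run completes in well under a minute on one core
while keeping every statistical check (binomial bands, weight-ranking
frequencies) adequately powered.
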