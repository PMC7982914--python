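"""SVM on precomputed kernels, metrics, ROC/AUC and cross-validation."""

import numpy as np
import pytest

from mkfuse.classify import (
    CVConfig,
    PipelineSettings,
    SVMConfig,
    compute_metrics,
    cross_validate,
    predict,
    roc_curve_auc,
    train_svm_precomputed,
)
from mkfuse.io import AlignedDataset, FeatureView, LabelSet
from mkfuse.kernels import KernelMatrix
from mkfuse.synthetic import SyntheticConfig, generate

from conftest import ids


def block_kernel(sizes, within=1.0, between=0.0):
    n = sum(sizes)
    M = np.full((n, n), between)
    r = 0
    for s in sizes:
        M[r : r + s, r : r + s] = within
        r += s
    return M


def labels_for(pattern):
    return LabelSet(ids(len(pattern)), list(pattern))


# ---------- SVM ----------

def test_block_kernel_separable_training_predictions():
    lab = labels_for("aaabbbccc")
    Kb = KernelMatrix(lab.sample_ids, block_kernel([3, 3, 3]))
    model = train_svm_precomputed(Kb, lab)
    y_pred, _ = predict(model, Kb.values)
    assert list(y_pred) == lab.labels


def test_identity_kernel_memorizes_training_labels():
    lab = labels_for("ababab")
    Ki = KernelMatrix(lab.sample_ids, np.eye(6))
    model = train_svm_precomputed(Ki, lab, SVMConfig(C=10.0))
    y_pred, _ = predict(model, np.eye(6))
    assert list(y_pred) == lab.labels


def test_all_ones_kernel_degenerates_to_majority():
    lab = labels_for("aaaab")  # majority a
    Ko = KernelMatrix(lab.sample_ids, np.ones((5, 5)))
    model = train_svm_precomputed(Ko, lab)
    y_pred, _ = predict(model, np.ones((3, 5)))
    assert set(y_pred) == {"a"}


def test_predict_row_independence_and_consistency():
    lab = labels_for("aaabbb")
    Kb = KernelMatrix(lab.sample_ids, block_kernel([3, 3]))
    model = train_svm_precomputed(Kb, lab)
    train_pred, _ = predict(model, Kb.values)
    # duplicating a test row duplicates its prediction
    row = Kb.values[0:1]
    twice, _ = predict(model, np.vstack([row, row]))
    assert twice[0] == twice[1] == train_pred[0]
    # a test sample aligned with the class-b block gets label b
    test_row = Kb.values[4:5]
    y, _ = predict(model, test_row)
    assert y[0] == "b"


def test_svm_input_validation():
    lab = labels_for("aaabbb")
    Kb = KernelMatrix(lab.sample_ids, block_kernel([3, 3]))
    with pytest.raises(ValueError, match="single class"):
        train_svm_precomputed(
            Kb, LabelSet(lab.sample_ids, ["a"] * 6, classes=["a", "b"])
        )
    model = train_svm_precomputed(Kb, lab)
    with pytest.raises(ValueError, match="columns"):
        predict(model, np.ones((2, 4)))


# ---------- metrics ----------

def test_perfect_prediction_metrics():
    y = ["a", "a", "b", "b"]
    rep = compute_metrics(y, y, ["a", "b"])
    assert rep.SN == rep.SP == rep.ACC == rep.MCC == 1.0


def test_binary_coin_flip_confusion():
    # TP=TN=FP=FN=1 with positive class 'b'
    y_true = ["b", "b", "a", "a"]
    y_pred = ["b", "a", "b", "a"]
    rep = compute_metrics(y_true, y_pred, ["a", "b"])
    assert rep.ACC == pytest.approx(0.5)
    assert rep.MCC == pytest.approx(0.0)
    assert rep.SN == pytest.approx(0.5)
    assert rep.SP == pytest.approx(0.5)


def test_multiclass_micro_recall_equals_accuracy(rng):
    classes = ["a", "b", "c"]
    for _ in range(100):
        y_true = rng.choice(classes, size=30)
        y_pred = rng.choice(classes, size=30)
        if len(set(y_true)) < 2:
            continue
        rep = compute_metrics(y_true, y_pred, classes)
        assert rep.SN == pytest.approx(rep.ACC, abs=1e-12)


def test_unseen_predicted_label_errors():
    with pytest.raises(ValueError, match="outside"):
        compute_metrics(["a", "b"], ["a", "z"], ["a", "b"])


def test_metrics_length_mismatch():
    with pytest.raises(ValueError, match="length"):
        compute_metrics(["a"], ["a", "b"], ["a", "b"])


# ---------- ROC / AUC ----------

def test_auc_perfect_ranking():
    y = ["a", "a", "b", "b"]
    scores = np.array([[1, -1], [2, -2], [-1, 1], [-2, 2]], dtype=float)
    pts, auc = roc_curve_auc(y, scores, ["a", "b"])
    assert auc == 1.0
    assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)


def test_auc_constant_scores_half():
    y = ["a", "b", "a", "b"]
    scores = np.zeros((4, 2))
    _, auc = roc_curve_auc(y, scores, ["a", "b"])
    assert auc == pytest.approx(0.5)


def auc_pair_oracle(pos_scores, neg_scores):
    """Mann-Whitney by explicit pair counting (ties count half)."""
    wins = ties = 0
    for p in pos_scores:
        for q in neg_scores:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos_scores) * len(neg_scores))


def test_auc_matches_pair_counting_oracle(rng):
    for _ in range(50):
        n = 5
        y = rng.choice(["a", "b"], size=n)
        if len(set(y)) < 2:
            continue
        s = np.round(rng.normal(size=n), 1)  # rounding forces ties
        scores = np.column_stack([-s, s])
        _, auc = roc_curve_auc(y, scores, ["a", "b"])
        oracle = auc_pair_oracle(s[y == "b"], s[y == "a"])
        assert auc == pytest.approx(oracle, abs=1e-12)


def test_roc_fpr_nondecreasing(rng):
    y = rng.choice(["a", "b"], size=40)
    s = rng.normal(size=40)
    pts, _ = roc_curve_auc(y, np.column_stack([-s, s]), ["a", "b"])
    fpr = [p[0] for p in pts]
    assert all(x <= y_ for x, y_ in zip(fpr, fpr[1:]))


def test_single_class_roc_errors():
    with pytest.raises(ValueError, match="single-class"):
        roc_curve_auc(["a", "a"], np.zeros((2, 2)), ["a", "b"])


# ---------- cross-validation ----------

def small_settings(method="hsic", seed=0, repeats=1):
    return PipelineSettings(
        view_dims={"gene": 5, "isoform": 5, "meth": 5},
        view_kernels={"gene": "tanimoto", "isoform": "pearson", "meth": "cosine"},
        mkl_method=method,
        cv=CVConfig(n_folds=2, seed=seed, repeats=repeats),
    )


def test_cv_deterministic_fold_assignment(easy_dataset):
    r1 = cross_validate(easy_dataset, small_settings())
    r2 = cross_validate(easy_dataset, small_settings())
    assert r1.extras["fold_assignments"] == r2.extras["fold_assignments"]
    assert r1.to_dict() == r2.to_dict()


def test_cv_partition_property(easy_dataset):
    rep = cross_validate(easy_dataset, small_settings())
    assignment = rep.extras["fold_assignments"][0]
    assert len(assignment) == easy_dataset.n_samples
    assert all(f in (0, 1) for f in assignment)
    # every sample appears in exactly one test fold
    assert sorted(rep.extras["pooled_sample_ids"]) == sorted(easy_dataset.sample_ids)


def test_cv_easy_data_high_accuracy(easy_dataset):
    rep = cross_validate(easy_dataset, small_settings())
    assert rep.ACC >= 0.95
    assert rep.confusion.sum() == easy_dataset.n_samples


def test_cv_confusion_counts_with_repeats(easy_dataset):
    rep = cross_validate(easy_dataset, small_settings(repeats=2))
    assert rep.confusion.sum() == 2 * easy_dataset.n_samples
    assert len(rep.per_fold) == 4


def test_cv_permutation_invariance(easy_dataset):
    """Shuffling the input sample order leaves pooled metrics unchanged."""
    perm = np.random.default_rng(3).permutation(easy_dataset.n_samples)
    sh_ids = [easy_dataset.sample_ids[i] for i in perm]
    shuffled = AlignedDataset(
        views=[v.subset(sh_ids) for v in easy_dataset.views],
        labels=easy_dataset.labels.subset(sh_ids),
    )
    r1 = cross_validate(easy_dataset, small_settings())
    r2 = cross_validate(shuffled, small_settings())
    assert r1.ACC == r2.ACC and r1.MCC == r2.MCC


def test_cv_class_smaller_than_folds_errors():
    ids_ = [f"s{i}" for i in range(5)]
    view = FeatureView("gene", ids_, np.random.default_rng(0).normal(size=(5, 4)))
    lab = LabelSet(ids_, ["a", "a", "a", "a", "b"])
    ds = AlignedDataset(views=[view], labels=lab)
    with pytest.raises(ValueError, match="fewer members"):
        cross_validate(
            ds, PipelineSettings(view_dims={"gene": 2}, cv=CVConfig(n_folds=2))
        )


def test_cv_label_permutation_null():
    """Shuffled labels give chance-level accuracy and near-zero MCC."""
    cfg = SyntheticConfig(
        n_per_class=[30, 30], n_views=2, ambient_dims=[60, 60],
        informative_dims=[5, 5], separation=[6.0, 6.0],
        view_names=["gene", "meth"], seed=11,
    )
    ds = generate(cfg)
    rng = np.random.default_rng(5)
    permuted = LabelSet(ds.sample_ids, list(rng.permutation(ds.labels.labels)))
    ds_null = AlignedDataset(views=ds.views, labels=permuted)
    settings = PipelineSettings(
        view_dims={"gene": 5, "meth": 5},
        view_kernels={"gene": "cosine", "meth": "tanimoto"},
        mkl_method="mean",
    )
    rep = cross_validate(ds_null, settings)
    n, p0 = 60, 0.5
    sigma = np.sqrt(p0 * (1 - p0) / n)
    assert abs(rep.ACC - p0) <= 3 * sigma + 1e-9
    assert abs(rep.MCC) <= 0.35


def test_cv_paper_mode_and_global_weights_run(easy_dataset):
    settings = small_settings()
    settings.pca_mode = "paper_mode"
    settings.weights_scope = "global"
    rep = cross_validate(easy_dataset, settings)
    assert rep.ACC >= 0.95
    # global scope: every fold logs the same weight vector
    w = rep.extras["fold_weights"]
    assert w[0] == w[1]
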