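"""Precomputed-kernel SVM, twofold cross-validation, and evaluation metrics.

The classifier consumes the fused Gram matrix directly (``kernel=
"precomputed"``).  Cross-validation is stratified k-fold (default k = 2);
within each fold the entire pipeline is refit on the training half: feature
scaling and PCA (in ``fold_safe`` mode), per-view kernels, fusion weights on
the training sub-Gram, and the SVM itself.  Test predictions are pooled
over folds ("micro pooling") for the headline metrics, with per-fold values
also reported.

Metrics: sensitivity SN = TP/(TP+FN), specificity SP = TN/(TN+FP), accuracy
ACC, Matthews correlation MCC, and ROC/AUC.  For more than two classes SN is
micro-averaged recall (numerically equal to ACC), SP is macro-averaged
one-vs-rest specificity, MCC is the Gorodkin multiclass generalization, and
AUC is the macro average of one-vs-rest AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .dimred import Scaler, fit_pca, transform
from .io import AlignedDataset, LabelSet
from .kernels import KernelMatrix, kernel_by_name, psd_project
from .mkl import KernelWeights, combine_kernels, compute_weights

__all__ = [
    "SVMConfig",
    "CVConfig",
    "PipelineSettings",
    "MetricsReport",
    "SVMModel",
    "train_svm_precomputed",
    "predict",
    "compute_metrics",
    "roc_curve_auc",
    "cross_validate",
]


@dataclass
class SVMConfig:
    C: float = 1.0
    multiclass_scheme: str = "one_vs_one"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.multiclass_scheme not in {"one_vs_one", "one_vs_rest"}:
            raise ValueError(
                f"unknown multiclass scheme {self.multiclass_scheme!r}"
            )


@dataclass
class CVConfig:
    n_folds: int = 2
    stratified: bool = True
    seed: int = 0
    repeats: int = 1

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class PipelineSettings:
    """Everything the per-fold pipeline needs beyond the data itself.

    ``view_dims`` / ``view_kernels`` map view names to PCA target dimension
    (None = no reduction) and kernel kind.  ``pca_mode`` is ``fold_safe``
    (fit inside the training fold) or ``paper_mode`` (fit once on all
    samples); ``weights_scope`` is ``per_fold`` or ``global``.
    """

    view_dims: dict = field(default_factory=dict)
    view_kernels: dict = field(default_factory=dict)
    mkl_method: str = "hsic"
    fkl_lambda: float = 1.0
    ideal_encoding: str = "onehot_FFt"
    pca_mode: str = "fold_safe"
    scale: str = "none"
    psd_repair: bool = True
    weights_scope: str = "per_fold"
    svm: SVMConfig = field(default_factory=SVMConfig)
    cv: CVConfig = field(default_factory=CVConfig)

    def __post_init__(self) -> None:
        if self.pca_mode not in {"fold_safe", "paper_mode"}:
            raise ValueError(f"unknown pca_mode {self.pca_mode!r}")
        if self.scale not in {"none", "zscore"}:
            raise ValueError(f"unknown scale mode {self.scale!r}")
        if self.weights_scope not in {"per_fold", "global"}:
            raise ValueError(f"unknown weights_scope {self.weights_scope!r}")


@dataclass
class MetricsReport:
    SN: float
    SP: float
    ACC: float
    MCC: float
    AUC: float | None
    confusion: np.ndarray
    classes: list[str]
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    per_fold: list[dict] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "SN": self.SN,
            "SP": self.SP,
            "ACC": self.ACC,
            "MCC": self.MCC,
            "AUC": self.AUC,
            "classes": self.classes,
            "confusion": self.confusion.astype(int).tolist(),
            "roc_points": [[float(a), float(b)] for a, b in self.roc_points],
            "per_fold": self.per_fold,
            **self.extras,
        }


@dataclass
class SVMModel:
    estimator: object
    classes: list[str]
    train_ids: list[str]
    scheme: str


def train_svm_precomputed(
    K_train: KernelMatrix, labels: LabelSet, cfg: SVMConfig | None = None
) -> SVMModel:
    """Fit an SVM on a precomputed training Gram matrix."""
    cfg = cfg or SVMConfig()
    if K_train.values.shape[0] != K_train.values.shape[1]:
        raise ValueError("training kernel must be square")
    if K_train.sample_ids != labels.sample_ids:
        raise ValueError("kernel and labels carry different sample orderings")
    y = labels.as_array()
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if cfg.multiclass_scheme == "one_vs_rest" and len(labels.classes) > 2:
        est = OneVsRestClassifier(SVC(kernel="precomputed", C=cfg.C))
    else:
        est = SVC(kernel="precomputed", C=cfg.C, decision_function_shape="ovr")
    est.fit(K_train.values, y)
    return SVMModel(
        estimator=est,
        classes=[str(c) for c in est.classes_],
        train_ids=list(K_train.sample_ids),
        scheme=cfg.multiclass_scheme,
    )


def predict(model: SVMModel, K_block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and per-class decision scores from a rectangular
    n_test x n_train kernel block whose columns follow the model's
    training ordering."""
    K_block = np.atleast_2d(np.asarray(K_block, dtype=float))
    if K_block.shape[1] != len(model.train_ids):
        raise ValueError(
            f"kernel block has {K_block.shape[1]} columns, "
            f"model was trained on {len(model.train_ids)} samples"
        )
    y_pred = model.estimator.predict(K_block).astype(object)
    dec = model.estimator.decision_function(K_block)
    if dec.ndim == 1:  # binary: score of classes[1]
        scores = np.column_stack([-dec, dec])
    else:
        scores = dec
    return y_pred, scores


def _binary_counts(cm: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) with class index 1 as positive."""
    tn, fp, fn, tp = cm.ravel()
    return int(tp), int(tn), int(fp), int(fn)


def compute_metrics(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    classes: Sequence[str],
    scores: np.ndarray | None = None,
) -> MetricsReport:
    """SN/SP/ACC/MCC (+ AUC and ROC points when scores are given).

    Binary problems take ``classes[1]`` as the positive class.  ``scores``
    is an n x n_classes decision matrix with columns ordered like
    ``classes``; AUC is omitted when it is absent.
    """
    y_true = np.asarray(list(y_true), dtype=object)
    y_pred = np.asarray(list(y_pred), dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    classes = [str(c) for c in classes]
    unseen = set(map(str, y_pred)) - set(classes)
    if unseen:
        raise ValueError(f"predicted labels outside class list: {sorted(unseen)}")
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    n = cm.sum()
    acc = float(np.trace(cm) / n)
    if len(classes) == 2:
        tp, tn, fp, fn = _binary_counts(cm)
        sn = tp / (tp + fn) if (tp + fn) else 0.0
        sp = tn / (tn + fp) if (tn + fp) else 0.0
    else:
        sn = acc  # micro-averaged recall pools all counts
        sps = []
        for i in range(len(classes)):
            tp_i = cm[i, i]
            fp_i = cm[:, i].sum() - tp_i
            fn_i = cm[i, :].sum() - tp_i
            tn_i = n - tp_i - fp_i - fn_i
            sps.append(tn_i / (tn_i + fp_i) if (tn_i + fp_i) else 0.0)
        sp = float(np.mean(sps))
    mcc = float(matthews_corrcoef(y_true, y_pred)) if len(set(y_true)) > 1 else 0.0
    auc: float | None = None
    roc_points: list[tuple[float, float]] = []
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        if scores.shape[0] != y_true.shape[0]:
            raise ValueError("scores and labels differ in length")
        try:
            roc_points, auc = roc_curve_auc(y_true, scores, classes)
        except ValueError:
            auc = None
    return MetricsReport(
        SN=float(sn), SP=float(sp), ACC=acc, MCC=mcc, AUC=auc,
        confusion=cm, classes=classes, roc_points=roc_points,
    )


def roc_curve_auc(
    y_true: Sequence[str],
    scores: np.ndarray,
    classes: Sequence[str],
) -> tuple[list[tuple[float, float]], float]:
    """ROC points and AUC.

    Binary: the standard curve with ``classes[1]`` positive; AUC equals the
    Mann-Whitney statistic of the positive-class scores.  Multiclass: AUC is
    the macro average of one-vs-rest AUCs, and the returned curve is the
    micro-pooled one-vs-rest ROC.
    """
    y_true = np.asarray(list(y_true), dtype=object)
    classes = [str(c) for c in classes]
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = np.column_stack([-scores, scores])
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC/AUC undefined for single-class y_true")
    if len(classes) == 2:
        s = scores[:, 1]
        fpr, tpr, _ = roc_curve(y_true, s, pos_label=classes[1])
        auc = float(roc_auc_score(y_true == classes[1], s))
        return list(zip(fpr.tolist(), tpr.tolist())), auc
    aucs = []
    for i, c in enumerate(classes):
        pos = y_true == c
        if pos.any() and (~pos).any():
            aucs.append(roc_auc_score(pos, scores[:, i]))
    auc = float(np.mean(aucs))
    # micro-pooled one-vs-rest curve
    indicator = np.concatenate([(y_true == c).astype(int) for c in classes])
    pooled = np.concatenate([scores[:, i] for i in range(len(classes))])
    fpr, tpr, _ = roc_curve(indicator, pooled)
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def _fold_kernels(
    dataset: AlignedDataset,
    settings: PipelineSettings,
    train_idx: np.ndarray,
) -> list[KernelMatrix]:
    """Build each view's full n x n kernel with preprocessing fitted on the
    training rows only (or on everything in paper_mode)."""
    kernels = []
    for view in dataset.views:
        work = view
        fit_rows = train_idx if settings.pca_mode == "fold_safe" else np.arange(view.n_samples)
        fit_view = type(view)(view.name, [view.sample_ids[i] for i in fit_rows],
                              view.matrix[fit_rows])
        if settings.scale == "zscore":
            scaler = Scaler.fit(fit_view)
            work = scaler.apply(view)
            fit_view = scaler.apply(fit_view)
        d = settings.view_dims.get(view.name)
        if d is not None:
            model = fit_pca(fit_view, d)
            work = transform(model, work)
        kind = settings.view_kernels.get(view.name, "cosine")
        kernels.append(kernel_by_name(kind)(work))
    return kernels


def cross_validate(
    dataset: AlignedDataset, settings: PipelineSettings | None = None
) -> MetricsReport:
    """Run the full pipeline under repeated stratified k-fold CV.

    Within each fold: (optionally) scale and PCA-reduce each view on the
    training half, build per-view kernels over all samples, compute fusion
    weights from the training sub-Gram, combine, PSD-repair, train the SVM
    on the training block and predict the held-out block.  Predictions are
    pooled over folds; per-fold metrics, fusion weights and fold assignments
    are attached to the report.
    """
    settings = settings or PipelineSettings()
    cv = settings.cv
    order = np.argsort(np.asarray(dataset.sample_ids, dtype=object))
    ids = [dataset.sample_ids[i] for i in order]
    y = dataset.labels.as_array()[order]
    classes = dataset.labels.classes
    counts = {c: int((y == c).sum()) for c in classes}
    too_small = [c for c, k in counts.items() if k < cv.n_folds]
    if too_small:
        raise ValueError(
            f"classes {too_small} have fewer members than n_folds={cv.n_folds}"
        )
    sorted_dataset = AlignedDataset(
        views=[v.subset(ids) for v in dataset.views],
        labels=dataset.labels.subset(ids),
    )

    global_weights: KernelWeights | None = None
    if settings.weights_scope == "global":
        all_kernels = _fold_kernels(sorted_dataset, settings, np.arange(len(ids)))
        global_weights = compute_weights(
            all_kernels, sorted_dataset.labels, settings.mkl_method,
            lam=settings.fkl_lambda, encoding=settings.ideal_encoding,
        )

    n = len(ids)
    pooled_ids: list[str] = []
    pooled_true: list[str] = []
    pooled_pred: list[str] = []
    pooled_scores: list[np.ndarray] = []
    per_fold: list[dict] = []
    fold_assignments: list[list[int]] = []
    weight_log: list[list[float]] = []

    for rep in range(cv.repeats):
        seed = cv.seed + rep
        if cv.stratified:
            splitter = StratifiedKFold(cv.n_folds, shuffle=True, random_state=seed)
            splits = splitter.split(np.zeros(n), y)
        else:
            from sklearn.model_selection import KFold

            splits = KFold(cv.n_folds, shuffle=True, random_state=seed).split(
                np.zeros(n)
            )
        assignment = [-1] * n
        for fold_no, (train_idx, test_idx) in enumerate(splits):
            for i in test_idx:
                assignment[i] = fold_no
            kernels = _fold_kernels(sorted_dataset, settings, train_idx)
            train_labels = sorted_dataset.labels.subset([ids[i] for i in train_idx])
            if global_weights is not None:
                weights = global_weights
            else:
                weights = compute_weights(
                    [K.restrict(train_idx) for K in kernels],
                    train_labels,
                    settings.mkl_method,
                    lam=settings.fkl_lambda,
                    encoding=settings.ideal_encoding,
                )
            combined = combine_kernels(kernels, weights)
            if settings.psd_repair:
                combined = psd_project(combined)
            K_train = combined.restrict(train_idx)
            model = train_svm_precomputed(K_train, train_labels, settings.svm)
            block = combined.values[np.ix_(test_idx, train_idx)]
            y_pred, raw_scores = predict(model, block)
            scores = _expand_scores(raw_scores, model.classes, classes)
            y_test = y[test_idx]
            pooled_ids.extend(ids[i] for i in test_idx)
            pooled_true.extend(y_test)
            pooled_pred.extend(y_pred)
            pooled_scores.append(scores)
            weight_log.append([float(w) for w in weights.weights])
            fold_report = compute_metrics(y_test, y_pred, classes, scores)
            per_fold.append(
                {
                    "repeat": rep,
                    "fold": fold_no,
                    "n_test": int(len(test_idx)),
                    "weights": [float(w) for w in weights.weights],
                    "SN": fold_report.SN,
                    "SP": fold_report.SP,
                    "ACC": fold_report.ACC,
                    "MCC": fold_report.MCC,
                    "AUC": fold_report.AUC,
                }
            )
        fold_assignments.append(assignment)

    report = compute_metrics(
        pooled_true, pooled_pred, classes, np.vstack(pooled_scores)
    )
    report.per_fold = per_fold
    report.extras = {
        "sample_ids": ids,
        "fold_assignments": fold_assignments,
        "fold_weights": weight_log,
        "view_names": [v.name for v in dataset.views],
        "pooled_sample_ids": pooled_ids,
        "pooled_predictions": list(map(str, pooled_pred)),
        "pooled_truth": list(map(str, pooled_true)),
    }
    return report


def _expand_scores(
    scores: np.ndarray, model_classes: list[str], all_classes: list[str]
) -> np.ndarray:
    """Map a model's per-class score columns into the full class ordering
    (absent classes get a very low score)."""
    scores = np.atleast_2d(scores)
    out = np.full((scores.shape[0], len(all_classes)), -np.inf)
    for j, c in enumerate(model_classes):
        out[:, all_classes.index(c)] = scores[:, j]
    return out
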