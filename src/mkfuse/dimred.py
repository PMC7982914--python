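"""PCA reduction of feature views.

Raw omics views have tens of thousands of features per sample; each view is
reduced to a small number of principal components before kernels are built.
Default target dimensions per view follow the pipeline presets (gene 40,
methylation 40, isoform 20 for the three-class kidney setting and 30 for the
two-class lung setting); all are overridable.

Two fitting modes exist at the pipeline level: ``fold_safe`` fits the PCA on
the training fold only (no test-set leakage; the default) and ``paper_mode``
fits once on all samples before cross-validation.  Optional feature
z-scoring is likewise fitted on training data only (:class:`Scaler`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .io import FeatureView

__all__ = ["PCAModel", "Scaler", "fit_pca", "transform", "fit_transform"]

DEFAULT_DIMS = {
    "kidney": {"gene": 40, "isoform": 20, "meth": 40},
    "lung": {"gene": 40, "isoform": 30, "meth": 40},
}


@dataclass
class Scaler:
    """Feature-wise z-scoring fitted on training data (std clamped away
    from zero so constant features pass through centered)."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, view: FeatureView) -> "Scaler":
        X = view.matrix
        sd = X.std(axis=0, ddof=0)
        return cls(mean=X.mean(axis=0), std=np.where(sd > 0, sd, 1.0))

    def apply(self, view: FeatureView) -> FeatureView:
        return FeatureView(
            view.name, view.sample_ids, (view.matrix - self.mean) / self.std
        )


@dataclass
class PCAModel:
    """Centered PCA: ``scores = (X - mean) @ components.T``.

    ``components`` rows are orthonormal; signs are fixed so the
    largest-magnitude loading of each component is positive, making the model
    deterministic.
    """

    mean: np.ndarray  # (p,)
    components: np.ndarray  # (d, p), rows orthonormal
    explained_variance_ratio: np.ndarray  # (d,), nonincreasing

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def n_features(self) -> int:
        return self.components.shape[1]


def fit_pca(view: FeatureView, d: int) -> PCAModel:
    """Fit centered PCA with ``d`` components on a view."""
    X = np.asarray(view.matrix, dtype=float)
    n, p = X.shape
    if not 1 <= d <= min(n - 1, p):
        raise ValueError(
            f"target dimension d={d} out of range [1, {min(n - 1, p)}] "
            f"for {n} samples x {p} features"
        )
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError(f"view {view.name!r}: zero-variance (constant) matrix")

    pca = PCA(n_components=d, svd_solver="full")
    pca.fit(X)
    components = pca.components_.copy()
    # deterministic sign: largest-|loading| coordinate made positive
    for i in range(components.shape[0]):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] = -components[i]
    return PCAModel(
        mean=pca.mean_.copy(),
        components=components,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def transform(model: PCAModel, view: FeatureView) -> FeatureView:
    """Project a view onto the model's components, centering with the
    *model's* mean (never the new data's)."""
    X = np.asarray(view.matrix, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"view has {X.shape[1]} features, model expects {model.n_features}"
        )
    scores = (X - model.mean) @ model.components.T
    return FeatureView(name=view.name, sample_ids=view.sample_ids, matrix=scores)


def fit_transform(view: FeatureView, d: int) -> FeatureView:
    return transform(fit_pca(view, d), view)
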