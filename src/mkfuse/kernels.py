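"""Sample-similarity kernels built from reduced feature views.

Three constructors turn an n x d score matrix into an n x n Gram matrix of
pairwise sample similarities:

* Tanimoto:  K[i,j] = x_i.x_j / (|x_i|^2 + |x_j|^2 - x_i.x_j), applied to the
  real-valued PCA scores as-is (not binarized).
* Pearson:   K[i,j] = cov(x_i, x_j) / (sigma_i sigma_j) over the d feature
  coordinates — i.e. the correlation of two *sample* vectors.
* Cosine:    K[i,j] = x_i.x_j / (|x_i| |x_j|).

Cosine and Pearson Gram matrices are PSD (Grams of normalized vectors); the
Tanimoto matrix need not be, and the combined kernel handed to the SVM is
passed through :func:`psd_project` (eigenvalue clipping) by default.

Degenerate rows are given continuity-motivated values: two zero vectors have
Tanimoto similarity 1, a zero vs. nonzero vector 0; a constant row has
Pearson similarity 0 to everything except itself; nonpositive Tanimoto
denominators yield similarity 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import FeatureView

__all__ = [
    "KernelMatrix",
    "tanimoto_kernel",
    "pearson_kernel",
    "cosine_kernel",
    "psd_project",
    "kernel_by_name",
    "write_kernel",
    "read_kernel",
]

KERNEL_KINDS = ("tanimoto", "pearson", "cosine")
_SYM_TOL = 1e-10


@dataclass
class KernelMatrix:
    """n x n symmetric similarity matrix aligned to a sample ordering."""

    sample_ids: list[str]
    values: np.ndarray
    kind: str = "combined"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"kernel shape {self.values.shape} does not match {n} sample ids"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite kernel values")
        if np.max(np.abs(self.values - self.values.T), initial=0.0) > _SYM_TOL:
            raise ValueError("kernel matrix is not symmetric")
        # exact symmetry by construction
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def restrict(self, idx: np.ndarray) -> "KernelMatrix":
        """Principal submatrix on integer index ``idx``."""
        idx = np.asarray(idx)
        return KernelMatrix(
            [self.sample_ids[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            self.kind,
        )


def _require_n(X: np.ndarray) -> None:
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to build a kernel")


def tanimoto_kernel(view: FeatureView) -> KernelMatrix:
    X = np.asarray(view.matrix, dtype=float)
    _require_n(X)
    G = X @ X.T
    sq = np.diag(G).copy()
    denom = sq[:, None] + sq[None, :] - G
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(denom > 0, G / np.where(denom > 0, denom, 1.0), 0.0)
    zero = sq == 0
    both_zero = np.logical_and.outer(zero, zero)
    K[both_zero] = 1.0
    return KernelMatrix(view.sample_ids, K, "tanimoto")


def pearson_kernel(view: FeatureView) -> KernelMatrix:
    X = np.asarray(view.matrix, dtype=float)
    _require_n(X)
    if X.shape[1] < 2:
        raise ValueError("pearson kernel needs at least 2 feature coordinates")
    Xc = X - X.mean(axis=1, keepdims=True)
    K = _normalized_gram(Xc)
    return KernelMatrix(view.sample_ids, K, "pearson")


def cosine_kernel(view: FeatureView) -> KernelMatrix:
    X = np.asarray(view.matrix, dtype=float)
    _require_n(X)
    K = _normalized_gram(X)
    return KernelMatrix(view.sample_ids, K, "cosine")


def _normalized_gram(X: np.ndarray) -> np.ndarray:
    """Gram of row-normalized X; zero rows get similarity 0 off-diagonal
    and 1 on the diagonal."""
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    Xn = X / safe[:, None]
    K = np.clip(Xn @ Xn.T, -1.0, 1.0)
    zero = norms == 0
    if zero.any():
        K[zero, :] = 0.0
        K[:, zero] = 0.0
    np.fill_diagonal(K, 1.0)
    return K


def kernel_by_name(kind: str):
    """Constructor lookup for config-driven pipelines."""
    table = {
        "tanimoto": tanimoto_kernel,
        "pearson": pearson_kernel,
        "cosine": cosine_kernel,
    }
    try:
        return table[kind]
    except KeyError:
        raise ValueError(
            f"unknown kernel kind {kind!r}; expected one of {KERNEL_KINDS}"
        ) from None


def psd_project(K: KernelMatrix, tol: float = 1e-10) -> KernelMatrix:
    """Clip negative eigenvalues to zero; a matrix already PSD (min
    eigenvalue >= -tol) is returned unchanged."""
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    V = K.values
    if np.max(np.abs(V - V.T), initial=0.0) > _SYM_TOL:
        raise ValueError("psd_project requires a symmetric matrix")
    w, U = np.linalg.eigh(V)
    if w.min() >= -tol:
        return K
    w = np.clip(w, 0.0, None)
    P = (U * w) @ U.T
    P = (P + P.T) / 2.0
    return KernelMatrix(K.sample_ids, P, K.kind)


def write_kernel(K: KernelMatrix, path: str | Path) -> None:
    """TSV with sample-id header row/column; the kind goes in a sidecar JSON."""
    path = Path(path)
    pd.DataFrame(K.values, index=K.sample_ids, columns=K.sample_ids).to_csv(
        path, sep="\t", index_label="id"
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(f'{{"kind": "{K.kind}", "n": {K.n}}}\n')


def read_kernel(path: str | Path) -> KernelMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    kind = "combined"
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        import json

        kind = json.loads(sidecar.read_text()).get("kind", "combined")
    return KernelMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float), kind)
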