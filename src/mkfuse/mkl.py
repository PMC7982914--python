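"""Multiple kernel learning: fusion weights and the combined kernel.

Given J per-view kernels K_1..K_J on the same samples, the fused kernel is
the convex combination K = sum_i beta_i K_i with the weight vector beta on
the probability simplex (sum beta_i = 1, beta_i >= 0).  Four weighting
rules are provided:

* ``mean`` — beta_i = 1/J.
* ``hsic`` — score each kernel against the label-derived ideal kernel with
  the Hilbert-Schmidt independence criterion
  HSIC(K_a, K_b) = (n-1)^-2 tr(K_a H K_b H), H = I - 11^T/n,
  then clip negatives to zero and L1-normalize.
* ``kta`` — same rule with kernel target alignment
  w = <K, K_ideal>_F / (|K|_F |K_ideal|_F).
* ``fkl`` — fast kernel learning: minimize |sum_i alpha_i K_i - Y|_F^2 +
  lambda |alpha|^2 over the simplex, which expands to the quadratic program
  min alpha^T (A + lambda I) alpha - 2 b^T alpha with A[i,j] = <K_i, K_j>_F
  and b[i] = <K_i, Y>_F.

The ideal (target) kernel is built from training labels: ``onehot_FFt``
(F F^T with one-hot class indicators F; entry 1 iff same class — valid for
any class count, the default) or ``signed_yyT`` (y y^T with y in {-1,+1};
binary problems only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .io import LabelSet
from .kernels import KernelMatrix

__all__ = [
    "KernelWeights",
    "IdealKernel",
    "centering_matrix",
    "ideal_kernel",
    "hsic",
    "kta_score",
    "alignment_weights",
    "fkl_weights",
    "mean_weights",
    "combine_kernels",
    "compute_weights",
]

MKL_METHODS = ("hsic", "kta", "fkl", "mean")
_SIMPLEX_TOL = 1e-8


@dataclass
class KernelWeights:
    """Nonnegative fusion weights summing to one."""

    weights: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1 or self.weights.size == 0:
            raise ValueError("weights must be a nonempty 1-D vector")
        if np.any(self.weights < -_SIMPLEX_TOL):
            raise ValueError("negative fusion weight")
        if abs(self.weights.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"weights sum to {self.weights.sum()}, expected 1")
        self.weights = np.clip(self.weights, 0.0, None)
        self.weights = self.weights / self.weights.sum()


@dataclass
class IdealKernel:
    """Label-derived target matrix the data kernels are scored against."""

    values: np.ndarray
    encoding: str


def centering_matrix(m: int) -> np.ndarray:
    """H = I - 11^T/m; idempotent and annihilates constant vectors."""
    if m < 1:
        raise ValueError("size must be positive")
    return np.eye(m) - np.full((m, m), 1.0 / m)


def ideal_kernel(labels: LabelSet, encoding: str = "onehot_FFt") -> IdealKernel:
    """Target matrix from labels: same-class structure as a Gram matrix."""
    y = labels.as_array()
    if encoding == "onehot_FFt":
        same = (y[:, None] == y[None, :]).astype(float)
        return IdealKernel(values=same, encoding=encoding)
    if encoding == "signed_yyT":
        if len(labels.classes) != 2:
            raise ValueError(
                f"signed_yyT encoding needs exactly 2 classes, "
                f"got {len(labels.classes)}"
            )
        s = np.where(y == labels.classes[1], 1.0, -1.0)
        return IdealKernel(values=np.outer(s, s), encoding=encoding)
    raise ValueError(f"unknown ideal-kernel encoding {encoding!r}")


def _as_matrix(K) -> np.ndarray:
    return K.values if hasattr(K, "values") else np.asarray(K, dtype=float)


def hsic(Ka, Kb) -> float:
    """(n-1)^-2 tr(K_a H K_b H) — empirical HSIC between two Gram matrices."""
    A, B = _as_matrix(Ka), _as_matrix(Kb)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError(f"size mismatch: {A.shape} vs {B.shape}")
    n = A.shape[0]
    if n < 2:
        raise ValueError("HSIC needs at least 2 samples")
    H = centering_matrix(n)
    return float(np.trace(A @ H @ B @ H) / (n - 1) ** 2)


def kta_score(Ka, Kideal) -> float:
    """<K, K_ideal>_F / (|K|_F |K_ideal|_F), in [-1, 1]."""
    A, B = _as_matrix(Ka), _as_matrix(Kideal)
    if A.shape != B.shape:
        raise ValueError(f"size mismatch: {A.shape} vs {B.shape}")
    na, nb = np.linalg.norm(A), np.linalg.norm(B)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm matrix in KTA")
    return float(np.sum(A * B) / (na * nb))


def _check_same_size(kernels: Sequence[KernelMatrix], n: int | None = None) -> int:
    if not kernels:
        raise ValueError("need at least one kernel")
    sizes = {K.n for K in kernels}
    if len(sizes) != 1:
        raise ValueError(f"kernels differ in size: {sorted(sizes)}")
    size = sizes.pop()
    if n is not None and size != n:
        raise ValueError(f"kernel size {size} does not match label count {n}")
    return size


def alignment_weights(
    kernels: Sequence[KernelMatrix],
    labels: LabelSet,
    scorer: str = "hsic",
    encoding: str = "onehot_FFt",
) -> KernelWeights:
    """Score each kernel against the ideal kernel, clip negatives to zero,
    L1-normalize.  All-zero scores fall back to uniform weights."""
    _check_same_size(kernels, len(labels.sample_ids))
    target = ideal_kernel(labels, encoding)
    if scorer == "hsic":
        score: Callable = lambda K: hsic(K, target)
    elif scorer == "kta":
        score = lambda K: kta_score(K, target)
    else:
        raise ValueError(f"unknown scorer {scorer!r}; expected 'hsic' or 'kta'")
    raw = np.array([score(K) for K in kernels], dtype=float)
    clipped = np.clip(raw, 0.0, None)
    total = clipped.sum()
    if total <= 0:
        weights = np.full(len(kernels), 1.0 / len(kernels))
    else:
        weights = clipped / total
    return KernelWeights(weights=weights, method=scorer)


def fkl_weights(
    kernels: Sequence[KernelMatrix],
    labels: LabelSet,
    lam: float = 1.0,
    encoding: str = "onehot_FFt",
    kkt_tol: float = 1e-6,
) -> KernelWeights:
    """Fast kernel learning weights: simplex-constrained ridge QP.

    Solves min_a a^T (A + lam I) a - 2 b^T a  s.t.  sum a = 1, a >= 0 with
    A[i,j] = <K_i, K_j>_F and b[i] = <K_i, Y>_F, via SLSQP with an analytic
    gradient and multi-start (uniform plus each simplex vertex).  The
    returned point is checked against the KKT conditions.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    _check_same_size(kernels, len(labels.sample_ids))
    J = len(kernels)
    Y = ideal_kernel(labels, encoding).values
    mats = [K.values for K in kernels]
    A = np.array([[np.sum(Ki * Kj) for Kj in mats] for Ki in mats])
    b = np.array([np.sum(Ki * Y) for Ki in mats])
    if J == 1:
        return KernelWeights(weights=np.array([1.0]), method="fkl")

    M = A + lam * np.eye(J)

    def objective(a: np.ndarray) -> float:
        return float(a @ M @ a - 2.0 * b @ a)

    def grad(a: np.ndarray) -> np.ndarray:
        return 2.0 * (M @ a) - 2.0 * b

    # scale the objective to O(1) so SLSQP tolerances behave uniformly
    scale = max(np.abs(M).max(), np.abs(b).max(), 1.0)
    starts = [np.full(J, 1.0 / J)]
    starts += [np.eye(J)[i] for i in range(J)]
    best, best_val = None, np.inf
    for x0 in starts:
        res = minimize(
            lambda a: objective(a) / scale,
            x0,
            jac=lambda a: grad(a) / scale,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * J,
            constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0}],
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if res.x is not None:
            a = np.clip(res.x, 0.0, None)
            a = a / a.sum()
            val = objective(a)
            if val < best_val:
                best, best_val = a, val
    if best is None:
        raise RuntimeError("FKL QP solver failed from every start")
    _check_kkt(M, b, best, scale, kkt_tol)
    return KernelWeights(weights=best, method="fkl")


def _check_kkt(M: np.ndarray, b: np.ndarray, a: np.ndarray, scale: float, tol: float) -> None:
    """Stationarity of the scaled Lagrangian on the simplex: for active
    coordinates the reduced gradient is constant; inactive ones cannot
    improve."""
    g = (2.0 * (M @ a) - 2.0 * b) / scale
    active = a > 1e-9
    mu = g[active].mean()  # multiplier of the equality constraint
    resid = np.abs(g[active] - mu).max(initial=0.0)
    viol = np.clip(mu - g[~active], 0.0, None).max(initial=0.0)
    if max(resid, viol) > tol:
        raise RuntimeError(
            f"FKL QP solution violates KKT conditions (residual {max(resid, viol):.2e})"
        )


def mean_weights(J: int) -> KernelWeights:
    """Uniform weights 1/J."""
    if J < 1:
        raise ValueError("need at least one kernel")
    return KernelWeights(weights=np.full(J, 1.0 / J), method="mean")


def combine_kernels(
    kernels: Sequence[KernelMatrix], weights: KernelWeights
) -> KernelMatrix:
    """Convex combination sum_i beta_i K_i; kind = 'combined'."""
    _check_same_size(kernels)
    if len(kernels) != weights.weights.size:
        raise ValueError(
            f"{len(kernels)} kernels but {weights.weights.size} weights"
        )
    ref = kernels[0].sample_ids
    for K in kernels[1:]:
        if K.sample_ids != ref:
            raise ValueError("kernels carry different sample orderings")
    V = np.zeros_like(kernels[0].values)
    for w, K in zip(weights.weights, kernels):
        V += w * K.values
    return KernelMatrix(list(ref), V, "combined")


def compute_weights(
    kernels: Sequence[KernelMatrix],
    labels: LabelSet,
    method: str,
    lam: float = 1.0,
    encoding: str = "onehot_FFt",
) -> KernelWeights:
    """Dispatch on the configured weighting method."""
    if method == "mean":
        return mean_weights(len(kernels))
    if method in {"hsic", "kta"}:
        return alignment_weights(kernels, labels, scorer=method, encoding=encoding)
    if method == "fkl":
        return fkl_weights(kernels, labels, lam=lam, encoding=encoding)
    raise ValueError(f"unknown MKL method {method!r}; expected one of {MKL_METHODS}")
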