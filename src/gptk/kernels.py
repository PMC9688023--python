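"""Kernels shared by KRR/SVR, and the PCA feature-reduction step.

The component count of the PCA step is itself a tuned hyperparameter, so the
decomposition is computed once at full rank and truncated by slicing.  PCA is
always fitted on training rows only and applied to validation rows with the
stored center and rotation — refitting on validation data would leak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigError, ShapeError, UndefinedStatisticError

__all__ = ["KernelSpec", "compute_kernel", "PCAState", "fit_pca", "transform_pca"]

_KERNELS = ("linear", "rbf", "cosine", "poly")


@dataclass(frozen=True)
class KernelSpec:
    """One kernel choice: linear, rbf, cosine, or poly.

    ``gamma`` is required for rbf/poly; ``degree`` (1-4) for poly.  The poly
    kernel is ``(gamma * <a, b> + 1) ** degree``.
    """

    name: str
    gamma: float | None = None
    degree: int | None = None

    def __post_init__(self):
        if self.name not in _KERNELS:
            raise ConfigError(f"unknown kernel {self.name!r}; choose from {_KERNELS}")
        if self.name in ("rbf", "poly"):
            if self.gamma is None or self.gamma <= 0:
                raise ConfigError(f"{self.name} kernel requires gamma > 0")
        if self.name == "poly":
            if self.degree is None or not 1 <= int(self.degree) <= 4:
                raise ConfigError("poly kernel requires degree in 1..4")


def compute_kernel(A: np.ndarray, B: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Kernel matrix K[i, j] = k(A[i], B[j])."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ShapeError(f"feature mismatch: {A.shape[1]} vs {B.shape[1]}")
    if spec.name == "linear":
        return A @ B.T
    if spec.name == "rbf":
        return np.exp(-spec.gamma * cdist(A, B, "sqeuclidean"))
    if spec.name == "poly":
        return (spec.gamma * (A @ B.T) + 1.0) ** int(spec.degree)
    # cosine
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise UndefinedStatisticError("cosine similarity undefined for zero-norm rows")
    return (A / na[:, None]) @ (B / nb[:, None]).T


@dataclass
class PCAState:
    """Centered-SVD principal components fitted on training rows.

    ``rotation`` is features x components with orthonormal columns;
    ``explained_variance`` the per-component sample variances (ddof=1),
    non-increasing.  Signs are fixed so each component's largest-magnitude
    loading is positive, making the decomposition reproducible.
    """

    center: np.ndarray
    rotation: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.rotation.shape[1]

    def truncate(self, k: int) -> "PCAState":
        """First-``k``-components view (no recomputation needed)."""
        if not 1 <= k <= self.n_components:
            raise ConfigError(f"k={k} outside 1..{self.n_components}")
        return PCAState(self.center, self.rotation[:, :k], self.explained_variance[:k])


def fit_pca(X: np.ndarray, k: int | None = None) -> PCAState:
    """Fit PCA by SVD of the centered training matrix.

    ``k`` defaults to full rank, bounded by min(n_samples - 1, n_features).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    max_k = min(n - 1, p)
    if k is None:
        k = max_k
    if not 1 <= k <= max_k:
        raise ConfigError(f"k={k} outside 1..{max_k} for a {n}x{p} matrix")
    center = X.mean(axis=0)
    _, s, vt = np.linalg.svd(X - center, full_matrices=False)
    rotation = vt[:k].T
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(rotation[np.abs(rotation).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    rotation = rotation * flip
    explained = (s[:k] ** 2) / (n - 1)
    return PCAState(center, rotation, explained)


def transform_pca(X: np.ndarray, state: PCAState) -> np.ndarray:
    """Project rows onto the fitted components: ``(X - center) @ rotation``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != state.center.shape[0]:
        raise ShapeError(
            f"{X.shape[1]} features but PCA was fitted on {state.center.shape[0]}"
        )
    return (X - state.center) @ state.rotation
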