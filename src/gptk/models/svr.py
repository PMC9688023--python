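"""ε-insensitive support vector regression, dual-solved by SMO.

The dual problem in the stacked variables a = (α, α*) ∈ [0, C]^{2n} is

    minimize  ½ aᵀQa + pᵀa   subject to  zᵀa = 0,

with z = (+1,…,+1,−1,…,−1), p = (ε − y, ε + y) and Q = zzᵀ ∘ K̃ (K̃ the kernel
matrix tiled 2×2).  Only samples outside the ε tube end with a nonzero net
weight β = α − α*; prediction is f(x) = Σ βᵢ k(xᵢ, x) + b.

The solver is sequential minimal optimization with maximal-violating-pair
working-set selection: at each step the most KKT-violating (i, j) pair is
updated analytically under the box and equality constraints, until the
violation gap falls below ``tol`` (default 1e-3) or the pair-update cap
(default 10⁴) is hit, which raises with the final KKT violation attached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigError, ConvergenceError, ShapeError
from ..kernels import KernelSpec, compute_kernel
from .preprocess import Preprocess

__all__ = ["SVRModel", "fit_svr", "predict_svr"]

_TAU = 1e-12


@dataclass
class SVRModel:
    spec: KernelSpec
    C: float
    epsilon: float
    dual_coefs: np.ndarray  # β = α − α*, one per training sample, |β| ≤ C
    intercept: float
    train_features: np.ndarray
    preprocess: Preprocess | None = None
    dual_objective: float = np.nan
    n_iter: int = 0


def _smo(K: np.ndarray, y: np.ndarray, C: float, epsilon: float, tol: float,
         max_iter: int) -> tuple[np.ndarray, float, float, int]:
    """Run SMO on the stacked dual; return (β, intercept, objective, n_iter)."""
    n = y.size
    z = np.concatenate([np.ones(n), -np.ones(n)])
    p = np.concatenate([epsilon - y, epsilon + y])
    a = np.zeros(2 * n)
    G = p.copy()  # gradient Qa + p at a = 0

    def q_col(t: int) -> np.ndarray:
        # column t of Q = zzᵀ ∘ K̃ without materializing the 2n × 2n matrix
        return z * (z[t] * np.concatenate([K[t % n], K[t % n]]))

    it = 0
    while True:
        zg = -z * G
        up = ((z > 0) & (a < C)) | ((z < 0) & (a > 0))
        low = ((z > 0) & (a > 0)) | ((z < 0) & (a < C))
        i = int(np.where(up, zg, -np.inf).argmax())
        j = int(np.where(low, zg, np.inf).argmin())
        gap = zg[i] - zg[j]
        if gap < tol:
            break
        if it >= max_iter:
            raise ConvergenceError(
                f"SMO hit the {max_iter}-update cap with KKT violation {gap:.3g}",
                kkt_violation=float(gap),
            )
        Ki, Kj = K[i % n], K[j % n]
        Qii = Ki[i % n]
        Qjj = Kj[j % n]
        Qij = z[i] * z[j] * Ki[j % n]
        ai_old, aj_old = a[i], a[j]
        if z[i] != z[j]:
            quad = max(Qii + Qjj + 2 * Qij, _TAU)
            delta = (-G[i] - G[j]) / quad
            diff = ai_old - aj_old
            ai, aj = ai_old + delta, aj_old + delta
            if diff > 0:
                if aj < 0:
                    aj, ai = 0.0, diff
            else:
                if ai < 0:
                    ai, aj = 0.0, -diff
            if diff > 0:
                if ai > C:
                    ai, aj = C, C - diff
            else:
                if aj > C:
                    aj, ai = C, C + diff
        else:
            quad = max(Qii + Qjj - 2 * Qij, _TAU)
            delta = (G[i] - G[j]) / quad
            s = ai_old + aj_old
            ai, aj = ai_old - delta, aj_old + delta
            if s > C:
                if ai > C:
                    ai, aj = C, s - C
                elif aj > C:
                    aj, ai = C, s - C
            else:
                if aj < 0:
                    aj, ai = 0.0, s
                elif ai < 0:
                    ai, aj = 0.0, s
            ai = min(max(ai, 0.0), C)
            aj = min(max(aj, 0.0), C)
        da_i, da_j = ai - ai_old, aj - aj_old
        if da_i == 0.0 and da_j == 0.0:
            break  # numerically stuck at the working pair; treat as converged
        a[i], a[j] = ai, aj
        G += q_col(i) * da_i + q_col(j) * da_j
        it += 1

    beta = a[:n] - a[n:]
    # intercept: −zG at free points; midpoint of the KKT bounds otherwise
    zg = -z * G
    free = (a > _TAU) & (a < C - _TAU)
    if free.any():
        b = float(np.mean(zg[free]))
    else:
        up = ((z > 0) & (a < C)) | ((z < 0) & (a > 0))
        low = ((z > 0) & (a > 0)) | ((z < 0) & (a < C))
        hi = np.where(up, zg, -np.inf).max()
        lo = np.where(low, zg, np.inf).min()
        b = float((hi + lo) / 2.0)
    objective = float(0.5 * a @ (G - p) + p @ a)  # ½aᵀQa + pᵀa since G = Qa + p
    return beta, b, objective, it


def fit_svr(
    X: np.ndarray,
    y: np.ndarray,
    spec: KernelSpec,
    C: float,
    epsilon: float = 0.1,
    tol: float = 1e-3,
    max_iter: int = 10_000,
    preprocess: Preprocess | None = None,
) -> SVRModel:
    if C <= 0:
        raise ConfigError("C must be > 0")
    if epsilon < 0:
        raise ConfigError("epsilon must be >= 0")
    if preprocess is not None:
        X = preprocess.transform_X(X)
        y = preprocess.transform_y(y)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    K = compute_kernel(X, X, spec)
    beta, b, obj, it = _smo(K, y, float(C), float(epsilon), tol, max_iter)
    return SVRModel(spec, float(C), float(epsilon), beta, b, X, preprocess, obj, it)


def predict_svr(model: SVRModel, Xnew: np.ndarray) -> np.ndarray:
    if model.preprocess is not None:
        Xnew = model.preprocess.transform_X(Xnew)
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[1] != model.train_features.shape[1]:
        raise ShapeError(
            f"{Xnew.shape[1]} features but model trained on "
            f"{model.train_features.shape[1]}"
        )
    pred = (
        compute_kernel(Xnew, model.train_features, model.spec) @ model.dual_coefs
        + model.intercept
    )
    if model.preprocess is not None:
        pred = model.preprocess.inverse_y(pred)
    return pred
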