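"""Kernel ridge regression solved in the dual.

The ridge objective penalizes squared errors with weight C; its dual solution
is ``w = (K + alpha I)^-1 y`` with ``alpha = 1/C``, which is the
parameterization exposed here (and the one hyperparameter tuners search,
"alpha" in 0-10).  The primal weight vector is never materialized: prediction
uses the representer identity ``f(x) = k(x, X_train) w``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from ..errors import ConfigError, NumericalError, ShapeError
from ..kernels import KernelSpec, compute_kernel
from .preprocess import Preprocess

__all__ = ["KRRModel", "fit_krr", "predict_krr"]


@dataclass
class KRRModel:
    spec: KernelSpec
    alpha: float
    dual_weights: np.ndarray
    train_features: np.ndarray
    preprocess: Preprocess | None = None


def fit_krr(
    X: np.ndarray,
    y: np.ndarray,
    spec: KernelSpec,
    alpha: float,
    preprocess: Preprocess | None = None,
) -> KRRModel:
    """Solve ``(K + alpha I) w = y`` on the (preprocessed) training features."""
    if alpha < 0:
        raise ConfigError("alpha must be >= 0")
    if preprocess is not None:
        X = preprocess.transform_X(X)
        y = preprocess.transform_y(y)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    K = compute_kernel(X, X, spec)
    A = K + alpha * np.eye(K.shape[0])
    try:
        if alpha > 0:
            c, low = linalg.cho_factor(A)
            w = linalg.cho_solve((c, low), y)
        else:
            w = linalg.solve(A, y)
    except linalg.LinAlgError as exc:
        raise NumericalError(
            f"kernel system is singular/ill-conditioned (alpha={alpha}); "
            "use alpha > 0"
        ) from exc
    resid = np.linalg.norm(A @ w - y)
    if not np.isfinite(resid) or resid > 1e-6 * max(np.linalg.norm(y), 1.0):
        raise NumericalError(
            f"kernel solve residual {resid:.3g} too large; alpha={alpha} "
            "likely too small for this kernel"
        )
    return KRRModel(spec, float(alpha), w, X, preprocess)


def predict_krr(model: KRRModel, Xnew: np.ndarray) -> np.ndarray:
    """``k(Xnew, X_train) w``, passed through the stored preprocessing."""
    if model.preprocess is not None:
        Xnew = model.preprocess.transform_X(Xnew)
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[1] != model.train_features.shape[1]:
        raise ShapeError(
            f"{Xnew.shape[1]} features but model trained on "
            f"{model.train_features.shape[1]}"
        )
    pred = compute_kernel(Xnew, model.train_features, model.spec) @ model.dual_weights
    if model.preprocess is not None:
        pred = model.preprocess.inverse_y(pred)
    return pred
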