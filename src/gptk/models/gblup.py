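"""GBLUP: genomic BLUP with a VanRaden relationship matrix and REML variances.

The mixed model is y = 1μ + g + e with g ~ N(0, σg² G) and e ~ N(0, σe² I),
where G = ZZᵀ / (2 Σ pᵢ(1 − pᵢ)) and Z holds allele-frequency-centered
dosages.  Variance components maximize the restricted likelihood: after one
eigendecomposition G = U D Uᵀ, the REML criterion is profiled down to a 1-D
function of λ = σe²/σg², scanned on a log grid and refined by bounded scalar
minimization, so each λ evaluation costs O(n).

Breeding values solve (G + λI) u = y − μ̂ (then GEBV = G u), and new
individuals are predicted through the cross-block of the relationship matrix
built with the *training* allele frequencies — never the validation ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from ..errors import DataError, NumericalError, ShapeError
from ..genotype_io import GenotypeMatrix

__all__ = [
    "VanRadenState",
    "vanraden_grm",
    "fit_vanraden",
    "vanraden_cross",
    "GBLUPModel",
    "fit_gblup",
    "predict_gblup",
]

_LAMBDA_BOUNDS = (1e-6, 1e6)


@dataclass
class VanRadenState:
    """Allele frequencies and scaling fixed by the training panel."""

    p: np.ndarray  # per-marker A1 allele frequency
    denom: float  # 2 Σ p(1−p)


def _dosage_array(g) -> np.ndarray:
    d = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    if np.isnan(d).any():
        raise DataError("GRM requires imputed (no-missing) dosages; run QC first")
    return d


def fit_vanraden(g) -> tuple[np.ndarray, VanRadenState]:
    """G = ZZᵀ / (2 Σ p(1−p)) with Z = dosages − 2p, p from this panel."""
    d = _dosage_array(g)
    p = d.mean(axis=0) / 2.0
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom == 0.0:
        raise NumericalError("all markers monomorphic: GRM denominator is zero")
    Z = d - 2.0 * p
    return (Z @ Z.T) / denom, VanRadenState(p, denom)


def vanraden_grm(g) -> np.ndarray:
    """The genomic relationship matrix alone (frequencies from the data)."""
    return fit_vanraden(g)[0]


def vanraden_cross(g_new, g_train, state: VanRadenState) -> np.ndarray:
    """Cross-block relating new individuals (rows) to training ones (columns)."""
    dn = _dosage_array(g_new)
    dt = _dosage_array(g_train)
    if dn.shape[1] != state.p.size or dt.shape[1] != state.p.size:
        raise ShapeError("marker count differs from the training GRM state")
    return ((dn - 2 * state.p) @ (dt - 2 * state.p).T) / state.denom


@dataclass
class GBLUPModel:
    sigma_g2: float
    sigma_e2: float
    lam: float  # σe²/σg²
    grm: np.ndarray
    gebv: np.ndarray
    mu: float
    # solution vector (G + λI)⁻¹(y − μ̂), reused for cross-block prediction
    alpha_vec: np.ndarray

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


def _reml_neg2ll(log_lam: float, d: np.ndarray, t: np.ndarray, o: np.ndarray,
                 n: int) -> float:
    lam = np.exp(log_lam)
    w = 1.0 / (d + lam)
    swo2 = float(np.sum(w * o * o))
    mu = float(np.sum(w * o * t) / swo2)
    r = t - mu * o
    sg2 = float(np.sum(w * r * r) / (n - 1))
    if sg2 <= 0:
        return np.inf
    return (n - 1) * np.log(sg2) + float(np.sum(np.log(d + lam))) + np.log(swo2)


def fit_gblup(y: np.ndarray, grm: np.ndarray, eig=None) -> GBLUPModel:
    """REML fit of (σg², σe²) and the resulting breeding values.

    ``eig=(d, U)`` may pass a precomputed eigendecomposition of the GRM, the
    expensive step when many traits are analyzed on one panel.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(grm, dtype=float)
    n = y.size
    if G.shape != (n, n):
        raise ShapeError(f"GRM shape {G.shape} does not match {n} phenotypes")
    if eig is None:
        if not np.allclose(G, G.T, atol=1e-8):
            raise DataError("GRM must be symmetric")
        d, U = np.linalg.eigh(G)
    else:
        d, U = eig
    if d.min() < -1e-6:
        raise NumericalError(f"GRM is not PSD (min eigenvalue {d.min():.3g})")
    d = np.clip(d, 0.0, None)
    t = U.T @ y
    o = U.T @ np.ones(n)

    lo, hi = np.log(_LAMBDA_BOUNDS[0]), np.log(_LAMBDA_BOUNDS[1])
    grid = np.linspace(lo, hi, 41)
    vals = [_reml_neg2ll(ll, d, t, o, n) for ll in grid]
    k = int(np.argmin(vals))
    a, b = grid[max(k - 1, 0)], grid[min(k + 1, grid.size - 1)]
    res = minimize_scalar(
        _reml_neg2ll, bounds=(a, b), args=(d, t, o, n), method="bounded",
        options={"xatol": 1e-8},
    )
    log_lam = float(res.x) if res.fun <= vals[k] else float(grid[k])
    if log_lam <= lo + 1e-9 or log_lam >= hi - 1e-9:
        warnings.warn(
            "REML likelihood is flat/boundary; lambda clamped to "
            f"[{_LAMBDA_BOUNDS[0]:g}, {_LAMBDA_BOUNDS[1]:g}]",
            stacklevel=2,
        )
    lam = float(np.exp(log_lam))

    w = 1.0 / (d + lam)
    swo2 = float(np.sum(w * o * o))
    mu = float(np.sum(w * o * t) / swo2)
    r = t - mu * o
    sg2 = float(np.sum(w * r * r) / (n - 1))
    se2 = lam * sg2
    alpha_vec = U @ (w * r)  # (G + λI)⁻¹ (y − μ̂)
    gebv = U @ (d * w * r)  # G (G + λI)⁻¹ (y − μ̂)
    return GBLUPModel(sg2, se2, lam, G, gebv, mu, alpha_vec)


def predict_gblup(model: GBLUPModel, grm_cross: np.ndarray) -> np.ndarray:
    """μ̂ + G_cross (G + λI)⁻¹ (y − μ̂) for new individuals."""
    Gc = np.atleast_2d(np.asarray(grm_cross, dtype=float))
    if Gc.shape[1] != model.alpha_vec.size:
        raise ShapeError(
            f"cross-block has {Gc.shape[1]} columns, training GRM "
            f"{model.alpha_vec.size}"
        )
    if model.sigma_g2 == 0.0:
        return np.full(Gc.shape[0], model.mu)
    return model.mu + Gc @ model.alpha_vec
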