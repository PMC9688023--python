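"""Default hyperparameter spaces and grids for KRR and SVR.

Ranges follow the tuning protocol this package implements: KRR searches over
kernel ∈ {cosine, rbf, linear}, ridge penalty alpha ∈ [0, 10], RBF bandwidth
gamma ∈ [1e-6, 1e-3] (log scale, active only for rbf), and the PCA component
count k ∈ [1, n]; SVR over kernel ∈ {rbf, linear, poly}, degree ∈ {1, 2, 3, 4}
(poly only), the same gamma range (rbf/poly), box constraint C ∈ [0.1, 100]
(log scale) and k.  The upper bound n for the component count is resolved at
tuning time as min(n_train − 1, n_features).  SVR's tube half-width ε is not
searched; it is fixed at 0.1 on z-scored responses.
"""

from __future__ import annotations

import numpy as np

from .hpo import Categorical, IntUniform, LogUniform, SearchSpace, Uniform

__all__ = [
    "krr_search_space",
    "svr_search_space",
    "default_krr_grid",
    "default_svr_grid",
]

GAMMA_RANGE = (1e-6, 1e-3)
ALPHA_RANGE = (0.0, 10.0)
C_RANGE = (0.1, 100.0)


def krr_search_space(max_components: int) -> SearchSpace:
    return SearchSpace(
        nodes={
            "kernel": Categorical(("cosine", "rbf", "linear")),
            "gamma": LogUniform(*GAMMA_RANGE),
            "alpha": Uniform(*ALPHA_RANGE),
            "n_components": IntUniform(1, max(max_components, 2)),
        },
        conditions={"gamma": ("kernel", frozenset({"rbf"}))},
    )


def svr_search_space(max_components: int) -> SearchSpace:
    return SearchSpace(
        nodes={
            "kernel": Categorical(("rbf", "linear", "poly")),
            "degree": Categorical((1, 2, 3, 4)),
            "gamma": LogUniform(*GAMMA_RANGE),
            "C": LogUniform(*C_RANGE),
            "n_components": IntUniform(1, max(max_components, 2)),
        },
        conditions={
            "degree": ("kernel", frozenset({"poly"})),
            "gamma": ("kernel", frozenset({"rbf", "poly"})),
        },
    )


def _k_grid(max_components: int, n_points: int = 4) -> list[int]:
    ks = np.unique(np.linspace(1, max(max_components, 2), n_points).round().astype(int))
    return [int(k) for k in ks]


def default_krr_grid(max_components: int) -> dict[str, list]:
    """3 kernels x 4 gamma (rbf only) x 5 alpha x 4 k -> 120 valid points."""
    return {
        "kernel": ["cosine", "rbf", "linear"],
        "gamma": [1e-6, 1e-5, 1e-4, 1e-3],
        "alpha": [0.01, 0.1, 1.0, 5.0, 10.0],
        "n_components": _k_grid(max_components),
    }


def default_svr_grid(max_components: int) -> dict[str, list]:
    return {
        "kernel": ["rbf", "linear", "poly"],
        "degree": [2, 3],
        "gamma": [1e-5, 1e-3],
        "C": [0.1, 1.0, 10.0, 100.0],
        "n_components": _k_grid(max_components, 3),
    }
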