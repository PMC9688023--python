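"""Fitted-model persistence: one self-describing ``.npz`` archive per model.

The archive carries the model kind, hyperparameters, dual weights / variance
components and the preprocessing constants needed to predict, so a model
saved by ``fit`` can be reloaded by ``predict`` in another process.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..errors import FormatError
from ..kernels import KernelSpec, PCAState
from .gblup import GBLUPModel
from .krr import KRRModel
from .preprocess import Preprocess
from .svr import SVRModel

__all__ = ["save_model", "load_model"]


def _header(model) -> dict:
    if isinstance(model, KRRModel):
        return {"kind": "krr", "spec": vars(model.spec), "alpha": model.alpha}
    if isinstance(model, SVRModel):
        return {
            "kind": "svr",
            "spec": vars(model.spec),
            "C": model.C,
            "epsilon": model.epsilon,
            "intercept": model.intercept,
        }
    if isinstance(model, GBLUPModel):
        return {
            "kind": "gblup",
            "sigma_g2": model.sigma_g2,
            "sigma_e2": model.sigma_e2,
            "lam": model.lam,
            "mu": model.mu,
        }
    raise FormatError(f"cannot serialize {type(model).__name__}")


def save_model(model, path: str | Path) -> None:
    arrays: dict[str, np.ndarray] = {}
    head = _header(model)
    pre = getattr(model, "preprocess", None)
    if pre is not None:
        head["preprocess"] = {"y_mean": pre.y_mean, "y_std": pre.y_std}
        if pre.pca is not None:
            arrays["pca_center"] = pre.pca.center
            arrays["pca_rotation"] = pre.pca.rotation
            arrays["pca_explained"] = pre.pca.explained_variance
    if isinstance(model, (KRRModel, SVRModel)):
        arrays["train_features"] = model.train_features
        arrays["weights"] = (
            model.dual_weights if isinstance(model, KRRModel) else model.dual_coefs
        )
    else:
        arrays["grm"] = model.grm
        arrays["gebv"] = model.gebv
        arrays["alpha_vec"] = model.alpha_vec
    arrays["header"] = np.frombuffer(json.dumps(head).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str | Path):
    with np.load(path) as data:
        head = json.loads(bytes(data["header"].tobytes()).decode())
        kind = head["kind"]
        pre = None
        if "preprocess" in head:
            pca = None
            if "pca_center" in data:
                pca = PCAState(
                    data["pca_center"], data["pca_rotation"], data["pca_explained"]
                )
            pre = Preprocess(
                pca=pca,
                y_mean=head["preprocess"]["y_mean"],
                y_std=head["preprocess"]["y_std"],
            )
        if kind == "krr":
            return KRRModel(
                KernelSpec(**head["spec"]),
                head["alpha"],
                data["weights"],
                data["train_features"],
                pre,
            )
        if kind == "svr":
            return SVRModel(
                KernelSpec(**head["spec"]),
                head["C"],
                head["epsilon"],
                data["weights"],
                head["intercept"],
                data["train_features"],
                pre,
            )
        if kind == "gblup":
            return GBLUPModel(
                head["sigma_g2"],
                head["sigma_e2"],
                head["lam"],
                data["grm"],
                data["gebv"],
                head["mu"],
                data["alpha_vec"],
            )
    raise FormatError(f"unknown model kind {kind!r}")
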