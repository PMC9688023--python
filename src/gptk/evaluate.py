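"""Assessment protocol: repeated k-fold CV with nested tuning, and rank tests.

Prediction accuracy is the Pearson correlation between predicted breeding
values and observed phenotypes in each held-out fold; the headline number for
one method x trait is the mean over ``n_repeats`` x ``n_folds`` replicates
(5-fold CV repeated 10 times gives the conventional fifty).

Hyperparameters are tuned inside each training split only, against seeded
80/20 inner holdouts, then the best configuration is refit on the whole
training split — the held-out fold never influences tuning, preprocessing or
variance components.  Methods are compared across datasets/traits with the
Friedman rank test and the Nemenyi critical difference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError, UndefinedStatisticError, GptkError
from .genotype_io import GenotypeMatrix, PhenotypeTable
from .kernels import KernelSpec, fit_pca
from .models import (
    Preprocess,
    fit_gblup,
    fit_krr,
    fit_svr,
    fit_vanraden,
    predict_gblup,
    predict_krr,
    predict_svr,
    vanraden_cross,
)
from .hpo import SearchSpace, optimize, random_search, grid_search, sample_prior
from .spaces import (
    default_krr_grid,
    default_svr_grid,
    krr_search_space,
    svr_search_space,
)

__all__ = [
    "CVProtocol",
    "CVResult",
    "RankComparison",
    "pearson_r",
    "make_folds",
    "run_cv",
    "friedman_test",
    "nemenyi_cd",
    "rank_comparison",
    "report",
]

SVR_EPSILON = 0.1  # tube half-width on z-scored responses
_ALPHA_CLAMP = 1e-8


def pearson_r(y: np.ndarray, yhat: np.ndarray) -> float:
    """Pearson correlation cov(y, ŷ) / (sd(y) sd(ŷ))."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise DataError("pearson_r needs two equal-length vectors")
    if y.size < 3:
        raise DataError("pearson_r needs at least 3 observations")
    if np.std(y) == 0 or np.std(yhat) == 0:
        raise UndefinedStatisticError("correlation undefined for constant vector")
    return float(np.corrcoef(y, yhat)[0, 1])


@dataclass(frozen=True)
class CVProtocol:
    n_folds: int = 5
    n_repeats: int = 10
    inner_holdout_fraction: float = 0.2
    n_inner_splits: int = 3
    seed: int = 0
    tuner: str = "tpe"  # tpe | random | grid | none
    budget: int = 200

    def __post_init__(self):
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.tuner not in ("tpe", "random", "grid", "none"):
            raise ConfigError(f"unknown tuner {self.tuner!r}")
        if not 0 < self.inner_holdout_fraction < 1:
            raise ConfigError("inner_holdout_fraction must be in (0, 1)")
        if self.n_inner_splits < 1:
            raise ConfigError("n_inner_splits must be >= 1")


def make_folds(sample_ids: list[str], protocol: CVProtocol) -> list[list[list[str]]]:
    """Per repeat, a seeded shuffle split into n_folds parts of near-equal size."""
    ids = list(sample_ids)
    if len(ids) < protocol.n_folds:
        raise ConfigError("fewer samples than folds")
    out = []
    for r in range(protocol.n_repeats):
        rng = np.random.default_rng([protocol.seed, r])
        perm = rng.permutation(len(ids))
        parts = np.array_split(perm, protocol.n_folds)
        out.append([[ids[i] for i in part] for part in parts])
    return out


@dataclass
class CVResult:
    method: str
    trait: str
    accuracies: np.ndarray  # n_repeats x n_folds
    chosen_configs: list = field(default_factory=list)
    fold_predictions: dict = field(default_factory=dict)
    tuning_histories: dict = field(default_factory=dict)  # (repeat, fold) -> [Trial]

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1))


def _krr_model_from(config, X, yv, pca_full):
    k = min(int(config["n_components"]), pca_full.n_components)
    pre = Preprocess.fit(X, yv, pca=pca_full.truncate(k))
    alpha = max(float(config["alpha"]), _ALPHA_CLAMP)
    return fit_krr(X, yv, _kernel_spec_from(config), alpha, preprocess=pre)


def _svr_model_from(config, X, yv, pca_full):
    k = min(int(config["n_components"]), pca_full.n_components)
    pre = Preprocess.fit(X, yv, pca=pca_full.truncate(k))
    return fit_svr(
        X, yv, _kernel_spec_from(config), float(config["C"]),
        epsilon=SVR_EPSILON, preprocess=pre,
    )


def _kernel_spec_from(config) -> KernelSpec:
    kernel = config["kernel"]
    if kernel == "rbf":
        return KernelSpec("rbf", gamma=float(config["gamma"]))
    if kernel == "poly":
        return KernelSpec("poly", gamma=float(config["gamma"]), degree=int(config["degree"]))
    return KernelSpec(kernel)


def _tune(method, Xtr, ytr, protocol, space, grid, inner_seed):
    """Pick a config on seeded inner holdouts of the training split.

    The objective is the Pearson accuracy averaged over ``n_inner_splits``
    random 80/20 holdouts, which stabilizes selection against the winner's
    curse of ranking many configurations on one small holdout.
    """
    n = Xtr.shape[0]
    n_hold = max(2, int(round(protocol.inner_holdout_fraction * n)))
    splits = []
    for s in range(protocol.n_inner_splits):
        rng = np.random.default_rng((*inner_seed, s))
        perm = rng.permutation(n)
        hold, fit_idx = perm[:n_hold], perm[n_hold:]
        Xfit, yfit = Xtr[fit_idx], ytr[fit_idx]
        pca_full = fit_pca(Xfit)
        mu, sd = float(yfit.mean()), float(yfit.std()) or 1.0
        splits.append(
            {
                "scores_fit": (Xfit - pca_full.center) @ pca_full.rotation,
                "scores_hold": (Xtr[hold] - pca_full.center) @ pca_full.rotation,
                "yfit_z": (yfit - mu) / sd,
                "yhold": ytr[hold],
                "max_k": pca_full.n_components,
            }
        )
    max_k = min(sp["max_k"] for sp in splits)
    if space is None:
        space = (krr_search_space if method == "krr" else svr_search_space)(max_k)
    if grid is None and protocol.tuner == "grid":
        grid = (default_krr_grid if method == "krr" else default_svr_grid)(max_k)

    def objective(config):
        spec = _kernel_spec_from(config)
        rs = []
        for sp in splits:
            k = min(int(config["n_components"]), sp["max_k"])
            Sfit, Shold = sp["scores_fit"][:, :k], sp["scores_hold"][:, :k]
            if method == "krr":
                model = fit_krr(
                    Sfit, sp["yfit_z"], spec, max(float(config["alpha"]), _ALPHA_CLAMP)
                )
                pred = predict_krr(model, Shold)
            else:
                model = fit_svr(
                    Sfit, sp["yfit_z"], spec, float(config["C"]), epsilon=SVR_EPSILON
                )
                pred = predict_svr(model, Shold)
            try:
                rs.append(pearson_r(sp["yhold"], pred))
            except UndefinedStatisticError:
                rs.append(0.0)
        return -float(np.mean(rs))

    tuner_seed = int(np.random.default_rng(inner_seed + (1,)).integers(2**31))
    if protocol.tuner == "tpe":
        best, history = optimize(objective, space, protocol.budget, tuner_seed)
    elif protocol.tuner == "random":
        best, history = random_search(objective, space, protocol.budget, tuner_seed)
    elif protocol.tuner == "grid":
        best, history = grid_search(objective, space, grid)
    else:
        config = sample_prior(space, tuner_seed)
        return config, []
    return best.config, history


def run_cv(
    g: GenotypeMatrix,
    y: PhenotypeTable,
    method: str,
    protocol: CVProtocol,
    space: SearchSpace | None = None,
    trait: str | None = None,
    grid: dict | None = None,
) -> CVResult:
    """Repeated k-fold CV of one method on one trait, nested tuning inside.

    Folds where the model cannot be fitted or produces constant predictions
    are recorded as accuracy 0 with a warning rather than aborting the run.
    """
    if method not in ("krr", "svr", "gblup"):
        raise ConfigError(f"unknown method {method!r}")
    if trait is None:
        if len(y.traits) != 1:
            raise ConfigError("trait must be named when the table has several")
        trait = next(iter(y.traits))
    y = y.aligned_to(g.sample_ids)
    yv_all = y.values(trait)
    keep = np.isfinite(yv_all)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} individuals with missing {trait}",
                      stacklevel=2)
    ids = [s for s, k in zip(g.sample_ids, keep) if k]
    X_all = g.dosages[keep]
    if np.isnan(X_all).any():
        col = np.nanmean(X_all, axis=0)
        idx = np.where(np.isnan(X_all))
        X_all = X_all.copy()
        X_all[idx] = col[idx[1]]
    yv = yv_all[keep]
    index = {s: i for i, s in enumerate(ids)}

    folds = make_folds(ids, protocol)
    acc = np.zeros((protocol.n_repeats, protocol.n_folds))
    chosen, fold_pred, histories = [], {}, {}
    for r, repeat_folds in enumerate(folds):
        for f, test_ids in enumerate(repeat_folds):
            test_idx = np.array([index[s] for s in test_ids])
            mask = np.ones(len(ids), dtype=bool)
            mask[test_idx] = False
            train_idx = np.where(mask)[0]
            Xtr, ytr = X_all[train_idx], yv[train_idx]
            Xte, yte = X_all[test_idx], yv[test_idx]
            config: dict = {}
            pred = np.full(len(test_ids), np.nan)
            try:
                if method == "gblup":
                    G, state = fit_vanraden(Xtr)
                    model = fit_gblup(ytr, G)
                    pred = predict_gblup(model, vanraden_cross(Xte, Xtr, state))
                    config = {"lambda": model.lam}
                else:
                    config, hist = _tune(
                        method, Xtr, ytr, protocol, space, grid,
                        inner_seed=(protocol.seed, 7, r, f),
                    )
                    histories[(r, f)] = hist
                    pca_full = fit_pca(Xtr)
                    if method == "krr":
                        model = _krr_model_from(config, Xtr, ytr, pca_full)
                        pred = predict_krr(model, Xte)
                    else:
                        model = _svr_model_from(config, Xtr, ytr, pca_full)
                        pred = predict_svr(model, Xte)
                a = pearson_r(yte, pred)
            except UndefinedStatisticError:
                warnings.warn(
                    f"constant predictions in repeat {r} fold {f}; accuracy set to 0",
                    stacklevel=2,
                )
                a = 0.0
            except GptkError as exc:
                warnings.warn(
                    f"{method} failed in repeat {r} fold {f} ({exc}); accuracy 0",
                    stacklevel=2,
                )
                a = 0.0
                pred = np.full(len(test_ids), np.nan)
            acc[r, f] = a
            chosen.append(config)
            fold_pred[(r, f)] = (list(test_ids), np.asarray(pred, dtype=float))
    return CVResult(method, trait, acc, chosen, fold_pred, histories)


# ---------------------------------------------------------------------------
# Friedman / Nemenyi method comparison
# ---------------------------------------------------------------------------

def friedman_test(accuracy_matrix: np.ndarray):
    """Friedman rank test over rows = datasets/traits, columns = methods.

    Higher accuracy gets the better (smaller) rank, ties averaged.  Returns
    (chi-square statistic, p-value, average ranks).
    """
    A = np.asarray(accuracy_matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] < 2 or A.shape[1] < 2:
        raise DataError("need at least 2 rows and 2 methods")
    if not np.isfinite(A).all():
        raise DataError("incomplete design: missing accuracy cells")
    N, k = A.shape
    ranks = np.vstack([stats.rankdata(-row) for row in A])
    avg = ranks.mean(axis=0)
    statistic = 12.0 * N / (k * (k + 1)) * (np.sum(avg**2) - k * (k + 1) ** 2 / 4.0)
    p = float(stats.chi2.sf(statistic, df=k - 1))
    return float(statistic), p, avg


# Studentized-range-derived q values (infinite df) for the Nemenyi test, k=2..10.
_NEMENYI_Q = {
    0.05: [1.960, 2.343, 2.569, 2.728, 2.850, 2.949, 3.031, 3.102, 3.164],
    0.10: [1.645, 2.052, 2.291, 2.459, 2.589, 2.693, 2.780, 2.855, 2.920],
}


def nemenyi_cd(k: int, N: int, alpha: float = 0.05) -> float:
    """Critical average-rank difference CD = q_α sqrt(k(k+1) / 6N)."""
    if alpha not in _NEMENYI_Q:
        raise ConfigError("alpha must be 0.05 or 0.10")
    if not 2 <= k <= 10:
        raise ConfigError("Nemenyi table covers k in 2..10")
    q = _NEMENYI_Q[alpha][k - 2]
    return float(q * np.sqrt(k * (k + 1) / (6.0 * N)))


@dataclass
class RankComparison:
    method_names: list[str]
    accuracy_matrix: np.ndarray
    average_ranks: np.ndarray
    friedman_statistic: float
    p_value: float
    nemenyi_cd: float
    alpha: float

    def differs(self, a: str, b: str) -> bool:
        i, j = self.method_names.index(a), self.method_names.index(b)
        if i == j:
            return False
        return abs(self.average_ranks[i] - self.average_ranks[j]) > self.nemenyi_cd


def rank_comparison(
    accuracy_matrix: np.ndarray, method_names: list[str], alpha: float = 0.05
) -> RankComparison:
    A = np.asarray(accuracy_matrix, dtype=float)
    stat, p, avg = friedman_test(A)
    cd = nemenyi_cd(A.shape[1], A.shape[0], alpha)
    return RankComparison(list(method_names), A, avg, stat, p, cd, alpha)


def report(
    results: list[CVResult],
    out_dir: str | Path,
    rank: RankComparison | None = None,
    metadata: dict | None = None,
) -> None:
    """Write the accuracy table, optional rank summary and run metadata."""
    if not results:
        raise DataError("nothing to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "method": r.method,
            "trait": r.trait,
            "mean_accuracy": r.mean,
            "sd": r.sd,
            "n_replicates": int(r.accuracies.size),
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(out / "accuracy.tsv", sep="\t", index=False,
                              float_format="%.6f")
    reps = []
    for r in results:
        for (rep, fold), a in np.ndenumerate(r.accuracies):
            reps.append({"method": r.method, "trait": r.trait, "repeat": rep,
                         "fold": fold, "accuracy": a})
    pd.DataFrame(reps).to_csv(out / "replicates.tsv", sep="\t", index=False,
                              float_format="%.17g")
    if rank is not None:
        pd.DataFrame(
            {
                "method": rank.method_names,
                "average_rank": rank.average_ranks,
            }
        ).to_csv(out / "ranks.tsv", sep="\t", index=False, float_format="%.6f")
        summary = {
            "friedman_statistic": rank.friedman_statistic,
            "p_value": rank.p_value,
            "nemenyi_cd": rank.nemenyi_cd,
            "alpha": rank.alpha,
        }
    else:
        summary = {}
    meta = {"metadata": metadata or {}, "rank_summary": summary}
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
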