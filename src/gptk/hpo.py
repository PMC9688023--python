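"""Hyperparameter optimization: tree-structured Parzen estimator and baselines.

The search space is a forest of named parameters (uniform, log-uniform,
integer, categorical) in which a parameter may be conditional on a parent's
categorical choice — e.g. a kernel bandwidth that only exists when the kernel
is RBF.  Three strategies share it:

* ``random_search`` — every trial drawn independently from the prior;
* ``grid_search``  — exhaustive product of user-supplied candidate values,
  restricted to valid conditional activations;
* ``optimize``     — TPE.  After ``n_startup`` prior-sampled trials, the
  history is split at the γ quantile of the loss into "good" and "bad"
  trials; each parameter gets two adaptive Parzen densities, l(x) from good
  observations and g(x) from bad ones; candidates are drawn from l and the
  one maximizing Σ log l − log g over its active parameters is evaluated.
  The density ratio l/g is monotone in the expected improvement of the
  underlying Bayesian model, so maximizing one maximizes the other.

Losses are minimized throughout; callers tuning a correlation pass its
negative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, ndtr, ndtri

from .errors import ConfigError

__all__ = [
    "Uniform",
    "LogUniform",
    "IntUniform",
    "Categorical",
    "SearchSpace",
    "Trial",
    "TPEConfig",
    "ParzenPair",
    "sample_prior",
    "split_trials",
    "build_parzen",
    "propose",
    "score_candidate",
    "suggest",
    "optimize",
    "random_search",
    "grid_search",
]


# ---------------------------------------------------------------------------
# Prior distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Uniform:
    low: float
    high: float

    def __post_init__(self):
        if not (np.isfinite(self.low) and np.isfinite(self.high) and self.low < self.high):
            raise ConfigError(f"uniform bounds ({self.low}, {self.high}) invalid")

    def sample(self, rng):
        return float(rng.uniform(self.low, self.high))

    def contains(self, x):
        return np.isreal(x) and self.low <= x <= self.high


@dataclass(frozen=True)
class LogUniform:
    low: float
    high: float

    def __post_init__(self):
        if not (0 < self.low < self.high and np.isfinite(self.high)):
            raise ConfigError(f"log-uniform bounds ({self.low}, {self.high}) invalid")

    def sample(self, rng):
        return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))

    def contains(self, x):
        return np.isreal(x) and self.low <= x <= self.high


@dataclass(frozen=True)
class IntUniform:
    low: int
    high: int  # inclusive

    def __post_init__(self):
        if self.low >= self.high:
            raise ConfigError(f"integer bounds ({self.low}, {self.high}) invalid")

    def sample(self, rng):
        return int(rng.integers(self.low, self.high + 1))

    def contains(self, x):
        return float(x) == int(x) and self.low <= x <= self.high


@dataclass(frozen=True)
class Categorical:
    choices: tuple
    weights: tuple | None = None  # prior weights, need not be normalized

    def __post_init__(self):
        if len(self.choices) == 0:
            raise ConfigError("categorical needs at least one choice")
        if self.weights is not None and len(self.weights) != len(self.choices):
            raise ConfigError("weights length must match choices")

    def _probs(self):
        w = np.ones(len(self.choices)) if self.weights is None else np.asarray(
            self.weights, dtype=float
        )
        return w / w.sum()

    def sample(self, rng):
        idx = rng.choice(len(self.choices), p=self._probs())
        return self.choices[int(idx)]

    def contains(self, x):
        return x in self.choices


NUMERIC = (Uniform, LogUniform, IntUniform)


# ---------------------------------------------------------------------------
# Search space
# ---------------------------------------------------------------------------

@dataclass
class SearchSpace:
    """Named parameters plus conditional activations forming a forest.

    ``conditions[name] = (parent, activating_values)`` means ``name`` exists
    only when the parent parameter (a categorical) takes one of the given
    values.
    """

    nodes: dict[str, Uniform | LogUniform | IntUniform | Categorical]
    conditions: dict[str, tuple[str, frozenset]] = field(default_factory=dict)

    def __post_init__(self):
        self.conditions = {
            k: (p, frozenset(v)) for k, (p, v) in self.conditions.items()
        }
        for child, (parent, _) in self.conditions.items():
            if child not in self.nodes or parent not in self.nodes:
                raise ConfigError(f"condition references unknown node {child}/{parent}")
        # one parent each => forest iff no cycles
        for start in self.conditions:
            seen, cur = {start}, start
            while cur in self.conditions:
                cur = self.conditions[cur][0]
                if cur in seen:
                    raise ConfigError("conditional structure contains a cycle")
                seen.add(cur)

    def topo_order(self) -> list[str]:
        order, placed = [], set()

        def visit(name):
            if name in placed:
                return
            if name in self.conditions:
                visit(self.conditions[name][0])
            placed.add(name)
            order.append(name)

        for name in self.nodes:
            visit(name)
        return order

    def is_active(self, name: str, config: dict) -> bool:
        if name not in self.conditions:
            return True
        parent, values = self.conditions[name]
        return parent in config and config[parent] in values

    def validate(self, config: dict) -> bool:
        """True iff config has exactly the active parameters, within bounds."""
        for name, dist in self.nodes.items():
            active = self.is_active(name, config)
            if active != (name in config):
                return False
            if active and not dist.contains(config[name]):
                return False
        return not (set(config) - set(self.nodes))


@dataclass
class Trial:
    """One evaluated configuration (inactive conditional parameters absent)."""

    config: dict
    loss: float
    index: int


@dataclass(frozen=True)
class TPEConfig:
    gamma_quantile: float = 0.25
    n_startup: int = 20
    n_candidates: int = 24
    bandwidth_floor_frac: float = 0.01  # of the node range, in modeling scale


def sample_prior(space: SearchSpace, seed_or_rng) -> dict:
    """One configuration from the prior (this is one random-search draw)."""
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator
    ) else seed_or_rng
    config: dict = {}
    for name in space.topo_order():
        if space.is_active(name, config):
            config[name] = space.nodes[name].sample(rng)
    return config


def split_trials(history: list[Trial], gamma_quantile: float) -> tuple[list[Trial], list[Trial]]:
    """Lowest-loss ``max(1, ceil(γ·n))`` trials are "good"; ties to earlier index."""
    if not history:
        raise ConfigError("cannot split an empty history")
    n_good = max(1, math.ceil(gamma_quantile * len(history)))
    ordered = sorted(history, key=lambda t: (t.loss, t.index))
    return ordered[:n_good], ordered[n_good:]


# ---------------------------------------------------------------------------
# Parzen densities
# ---------------------------------------------------------------------------

class _NumericParzen:
    """Truncated-Gaussian mixture over [low, high] in the modeling scale.

    One equally weighted component per observation plus one prior-wide
    uniform component; bandwidths are adaptive (the larger neighbor gap in
    sorted order, bounds included, floored at a fraction of the range).
    Log-uniform nodes are modeled in log space; integer nodes discretize the
    continuous mixture onto the integer grid.
    """

    def __init__(self, obs, dist, floor_frac=0.01):
        self.dist = dist
        self.log_scale = isinstance(dist, LogUniform)
        self.integer = isinstance(dist, IntUniform)
        lo, hi = float(dist.low), float(dist.high)
        if self.log_scale:
            lo, hi = np.log(lo), np.log(hi)
        if self.integer:
            lo, hi = lo - 0.5, hi + 0.5  # each integer owns a unit cell
        self.lo, self.hi = lo, hi
        obs = np.asarray(obs, dtype=float)
        if np.any((obs < dist.low) | (obs > dist.high)):
            raise ConfigError("observation outside node bounds")
        mus = np.log(obs) if self.log_scale else obs
        order = np.argsort(mus)
        mus = mus[order]
        if mus.size:
            padded = np.concatenate([[lo], mus, [hi]])
            gaps = np.maximum(padded[2:] - padded[1:-1], padded[1:-1] - padded[:-2])
            sigmas = np.clip(gaps, floor_frac * (hi - lo), hi - lo)
        else:
            sigmas = np.empty(0)
        self.mus, self.sigmas = mus, sigmas
        n = mus.size
        self.weights = np.full(n + 1, 1.0 / (n + 1))  # last = prior component
        if n:
            self._lowc = ndtr((lo - mus) / sigmas)
            self._mass = np.maximum(ndtr((hi - mus) / sigmas) - self._lowc, 1e-300)
        if self.integer:
            grid = np.arange(dist.low, dist.high + 1)
            pmf = self._cont_cdf(grid + 0.5) - self._cont_cdf(grid - 0.5)
            self._grid, self._pmf = grid, pmf / pmf.sum()

    # -- continuous mixture pieces (modeling scale) --
    def _cont_logpdf(self, u):
        prior = np.log(self.weights[-1]) - np.log(self.hi - self.lo)
        if not self.mus.size:
            return float(prior)
        z = (-0.5 * ((u - self.mus) / self.sigmas) ** 2 - 0.9189385332046727) - np.log(self.sigmas)
        z = z + np.log(self.weights[:-1]) - np.log(self._mass)
        return float(logsumexp(np.append(z, prior)))

    def _cont_cdf(self, u):
        u = np.asarray(u, dtype=float)
        total = self.weights[-1] * (u - self.lo) / (self.hi - self.lo)
        if self.mus.size:
            comp = (ndtr((u[..., None] - self.mus) / self.sigmas) - self._lowc)
            total = total + (comp / self._mass) @ self.weights[:-1]
        return total

    def _sample_cont(self, rng):
        k = rng.choice(self.weights.size, p=self.weights)
        if k == self.weights.size - 1:
            return rng.uniform(self.lo, self.hi)
        mu, s = self.mus[k], self.sigmas[k]
        a, b = (self.lo - mu) / s, (self.hi - mu) / s
        u = rng.uniform(ndtr(a), ndtr(b))
        return mu + s * ndtri(u)

    # -- public interface (natural scale) --
    def sample(self, rng):
        if self.integer:
            return int(rng.choice(self._grid, p=self._pmf))
        u = self._sample_cont(rng)
        x = np.exp(u) if self.log_scale else u
        return float(np.clip(x, self.dist.low, self.dist.high))

    def logpdf(self, x):
        if self.integer:
            i = int(x) - self.dist.low
            return float(np.log(np.maximum(self._pmf[i], 1e-300)))
        u = np.log(x) if self.log_scale else float(x)
        lp = self._cont_logpdf(u)
        if self.log_scale:
            lp -= u  # change of variables d(log x) = dx / x
        return lp


class _CategoricalParzen:
    """Prior counts (scaled to unit mean) plus observation counts, normalized."""

    def __init__(self, obs, dist):
        w = np.ones(len(dist.choices)) if dist.weights is None else np.asarray(
            dist.weights, dtype=float
        )
        counts = w / w.mean()
        for x in obs:
            if x not in dist.choices:
                raise ConfigError(f"observation {x!r} outside categorical choices")
            counts[dist.choices.index(x)] += 1
        self.dist = dist
        self.probs = counts / counts.sum()

    def sample(self, rng):
        return self.dist.choices[int(rng.choice(len(self.dist.choices), p=self.probs))]

    def logpdf(self, x):
        return float(np.log(self.probs[self.dist.choices.index(x)]))


def build_parzen(observations, dist, floor_frac: float = 0.01):
    """Adaptive Parzen density for one node; with no observations it is the prior."""
    if isinstance(dist, Categorical):
        return _CategoricalParzen(observations, dist)
    return _NumericParzen(observations, dist, floor_frac)


@dataclass
class ParzenPair:
    """Per-node good/bad densities l(x), g(x) at quantile γ."""

    good: dict
    bad: dict
    gamma_quantile: float


def _fit_pair(history, space, cfg: TPEConfig) -> ParzenPair:
    good, bad = split_trials(history, cfg.gamma_quantile)
    densities = {}
    for which, trials in (("good", good), ("bad", bad)):
        per_node = {}
        for name, dist in space.nodes.items():
            obs = [t.config[name] for t in trials if name in t.config]
            per_node[name] = build_parzen(obs, dist, cfg.bandwidth_floor_frac)
        densities[which] = per_node
    return ParzenPair(densities["good"], densities["bad"], cfg.gamma_quantile)


def _sample_from(densities, space, rng) -> dict:
    config: dict = {}
    for name in space.topo_order():
        if space.is_active(name, config):
            config[name] = densities[name].sample(rng)
    return config


def score_candidate(config: dict, pair: ParzenPair) -> float:
    """Σ over the candidate's active nodes of log l(x) − log g(x)."""
    return sum(
        pair.good[name].logpdf(x) - pair.bad[name].logpdf(x)
        for name, x in config.items()
    )


def propose(
    history: list[Trial],
    space: SearchSpace,
    seed_or_rng,
    cfg: TPEConfig = TPEConfig(),
) -> tuple[dict, list[dict], list[float], ParzenPair | None]:
    """Full TPE proposal: (chosen config, candidate set, scores, densities).

    During startup (or when the split leaves no "bad" trials, e.g. γ = 1)
    the candidate set is a single draw — from the prior, respectively from
    the all-observation Parzen density — and no scoring happens.
    """
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator
    ) else seed_or_rng
    if len(history) < cfg.n_startup:
        c = sample_prior(space, rng)
        return c, [c], [0.0], None
    pair = _fit_pair(history, space, cfg)
    _, bad_trials = split_trials(history, cfg.gamma_quantile)
    if not bad_trials:
        c = _sample_from(pair.good, space, rng)
        return c, [c], [0.0], pair
    candidates = [_sample_from(pair.good, space, rng) for _ in range(cfg.n_candidates)]
    scores = [score_candidate(c, pair) for c in candidates]
    return candidates[int(np.argmax(scores))], candidates, scores, pair


def suggest(
    history: list[Trial],
    space: SearchSpace,
    seed_or_rng,
    cfg: TPEConfig = TPEConfig(),
) -> dict:
    """Propose the next configuration (prior sample during startup)."""
    return propose(history, space, seed_or_rng, cfg)[0]


# ---------------------------------------------------------------------------
# Optimization loops
# ---------------------------------------------------------------------------

def _run_loop(objective, space, max_evals, seed, proposer) -> tuple[Trial, list[Trial]]:
    if max_evals < 1:
        raise ConfigError("max_evals must be >= 1")
    rng = np.random.default_rng(seed)
    history: list[Trial] = []
    for i in range(max_evals):
        config = proposer(history, rng)
        try:
            loss = float(objective(config))
        except Exception as exc:  # noqa: BLE001 - a failed trial must not kill the run
            warnings.warn(f"trial {i} failed ({exc!r}); recorded as +inf", stacklevel=3)
            loss = np.inf
        history.append(Trial(config, loss, i))
    best = min(history, key=lambda t: (t.loss, t.index))
    return best, history


def optimize(
    objective,
    space: SearchSpace,
    max_evals: int,
    seed: int,
    cfg: TPEConfig = TPEConfig(),
) -> tuple[Trial, list[Trial]]:
    """TPE loop: exactly ``max_evals`` evaluations, deterministic given seed."""
    return _run_loop(
        objective, space, max_evals, seed,
        lambda history, rng: suggest(history, space, rng, cfg),
    )


def random_search(objective, space: SearchSpace, max_evals: int, seed: int):
    """Prior-only baseline at the same budget."""
    return _run_loop(
        objective, space, max_evals, seed,
        lambda history, rng: sample_prior(space, rng),
    )


def grid_search(objective, space: SearchSpace, grid_spec: dict[str, list]):
    """Exhaustive product of the given per-node values, conditionals respected."""
    for name, values in grid_spec.items():
        if name not in space.nodes:
            raise ConfigError(f"grid names unknown node {name!r}")
        for v in values:
            if not space.nodes[name].contains(v):
                raise ConfigError(f"grid value {v!r} outside bounds of {name!r}")
    order = [n for n in space.topo_order() if n in grid_spec]

    configs: list[dict] = []

    def expand(i, partial):
        if i == len(order):
            configs.append(dict(partial))
            return
        name = order[i]
        if space.is_active(name, partial):
            for v in grid_spec[name]:
                partial[name] = v
                expand(i + 1, partial)
                del partial[name]
        else:
            expand(i + 1, partial)

    expand(0, {})
    history = []
    for i, config in enumerate(configs):
        try:
            loss = float(objective(config))
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"grid point {i} failed ({exc!r}); recorded as +inf",
                          stacklevel=2)
            loss = np.inf
        history.append(Trial(config, loss, i))
    best = min(history, key=lambda t: (t.loss, t.index))
    return best, history
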