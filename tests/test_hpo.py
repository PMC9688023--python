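"""Hyperparameter optimization: priors, Parzen densities, TPE and baselines."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from gptk.errors import ConfigError
from gptk.hpo import (
    Categorical,
    IntUniform,
    LogUniform,
    SearchSpace,
    TPEConfig,
    Trial,
    Uniform,
    build_parzen,
    grid_search,
    optimize,
    propose,
    random_search,
    sample_prior,
    score_candidate,
    split_trials,
    suggest,
)
from gptk.spaces import default_krr_grid, krr_search_space, svr_search_space


class TestPriorSampling:
    def test_single_choice_categorical(self):
        space = SearchSpace(nodes={"k": Categorical(("only",))})
        assert all(sample_prior(space, s) == {"k": "only"} for s in range(10))

    def test_log_uniform_median_is_geometric_mean(self):
        dist = LogUniform(0.1, 100.0)
        rng = np.random.default_rng(0)
        draws = [dist.sample(rng) for _ in range(10_000)]
        assert np.median(draws) == pytest.approx(math.sqrt(10), rel=0.15)

    def test_conditional_activation(self):
        space = svr_search_space(50)
        for s in range(300):
            c = sample_prior(space, s)
            assert ("degree" in c) == (c["kernel"] == "poly")
            assert ("gamma" in c) == (c["kernel"] in ("rbf", "poly"))
            assert space.validate(c)

    def test_cycle_rejected(self):
        with pytest.raises(ConfigError, match="cycle"):
            SearchSpace(
                nodes={"a": Categorical((1, 2)), "b": Categorical((1, 2))},
                conditions={"a": ("b", {1}), "b": ("a", {1})},
            )


class TestSplitTrials:
    def test_quantile_split(self):
        hist = [Trial({"x": i}, float(i + 1), i) for i in range(8)]
        good, bad = split_trials(hist, 0.25)
        assert sorted(t.loss for t in good) == [1.0, 2.0]
        assert len(bad) == 6

    def test_single_trial_floor(self):
        hist = [Trial({}, 5.0, 0)]
        good, bad = split_trials(hist, 0.25)
        assert good == [hist[0]] and bad == []

    def test_ties_resolved_by_index(self):
        hist = [Trial({"x": i}, 1.0, i) for i in range(8)]
        good, _ = split_trials(hist, 0.25)
        assert [t.index for t in good] == [0, 1]


class TestParzen:
    def test_no_observations_equals_prior(self):
        dens = build_parzen([], Uniform(0, 4))
        xs = np.linspace(0.1, 3.9, 7)
        for x in xs:
            assert dens.logpdf(x) == pytest.approx(np.log(0.25), abs=1e-10)

    def test_categorical_count_arithmetic(self):
        dens = build_parzen(["a", "a", "b"], Categorical(("a", "b", "c")))
        np.testing.assert_allclose(dens.probs, [3 / 6, 2 / 6, 1 / 6])

    @pytest.mark.parametrize(
        "dist", [Uniform(-2, 5), LogUniform(1e-3, 10.0)], ids=["uniform", "log"]
    )
    def test_numeric_density_normalized(self, dist):
        rng = np.random.default_rng(1)
        obs = [dist.sample(rng) for _ in range(12)]
        dens = build_parzen(obs, dist)
        total, err = quad(
            lambda x: np.exp(dens.logpdf(x)), dist.low, dist.high, limit=300
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_integer_density_sums_to_one(self):
        dist = IntUniform(1, 40)
        dens = build_parzen([3, 3, 17, 30], dist)
        total = sum(np.exp(dens.logpdf(v)) for v in range(1, 41))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_observation_outside_bounds_rejected(self):
        with pytest.raises(ConfigError):
            build_parzen([11.0], Uniform(0, 10))

    def test_samples_stay_in_bounds(self):
        rng = np.random.default_rng(2)
        dens = build_parzen([0.01, 9.9], Uniform(0, 10))
        draws = [dens.sample(rng) for _ in range(500)]
        assert min(draws) >= 0 and max(draws) <= 10


class TestSuggest:
    def test_startup_delegates_to_prior(self):
        space = krr_search_space(20)
        hist = [Trial(sample_prior(space, s), 1.0, s) for s in range(5)]
        cfg = TPEConfig(n_startup=20)
        assert suggest(hist, space, 3, cfg) == sample_prior(space, 3)

    def test_returned_candidate_maximizes_log_ratio(self):
        space = svr_search_space(30)
        rng = np.random.default_rng(4)
        hist = [
            Trial(sample_prior(space, int(rng.integers(2**31))), float(rng.uniform()), i)
            for i in range(40)
        ]
        chosen, candidates, scores, pair = propose(hist, space, 11)
        rescored = [score_candidate(c, pair) for c in candidates]
        np.testing.assert_allclose(rescored, scores, atol=1e-12)
        assert chosen == candidates[int(np.argmax(rescored))]

    def test_suggestions_concentrate_near_good_trials(self):
        space = SearchSpace(nodes={"x": Uniform(0, 10)})
        rng = np.random.default_rng(5)
        hist = []
        i = 0
        for _ in range(10):  # good cluster in [2, 3]
            hist.append(Trial({"x": float(rng.uniform(2, 3))}, 0.1, i)); i += 1
        for _ in range(30):  # bad cluster in [7, 9]
            hist.append(Trial({"x": float(rng.uniform(7, 9))}, 5.0, i)); i += 1
        inside = sum(
            1.5 <= suggest(hist, space, 100 + s)["x"] <= 3.5 for s in range(100)
        )
        assert inside >= 80

    def test_gamma_one_samples_from_all_observation_density(self):
        """With everything 'good' the proposal is a draw from the Parzen fit."""
        space = SearchSpace(nodes={"x": Uniform(0, 10)})
        rng = np.random.default_rng(6)
        hist = [
            Trial({"x": float(rng.uniform(4, 6))}, float(rng.uniform()), i)
            for i in range(30)
        ]
        cfg = TPEConfig(gamma_quantile=1.0, n_startup=1)
        tpe_draws = [suggest(hist, space, 1000 + s, cfg)["x"] for s in range(400)]
        dens = build_parzen([t.config["x"] for t in hist], Uniform(0, 10))
        rng2 = np.random.default_rng(7)
        direct = [dens.sample(rng2) for _ in range(400)]
        assert stats.ks_2samp(tpe_draws, direct).pvalue > 0.01


class TestOptimize:
    def test_quadratic_benchmark(self):
        space = SearchSpace(nodes={"x": Uniform(0, 10)})
        close = 0
        for s in range(20):
            best, hist = optimize(lambda c: (c["x"] - 3) ** 2, space, 200, seed=s)
            assert len(hist) == 200
            close += abs(best.config["x"] - 3) < 0.1
        assert close >= 18  # ≥90% of seeds

    def test_single_evaluation(self):
        space = SearchSpace(nodes={"x": Uniform(0, 1)})
        best, hist = optimize(lambda c: c["x"], space, 1, seed=0)
        assert len(hist) == 1 and best is hist[0]

    def test_beats_or_matches_random_search(self):
        def branin_like(c):
            x, y = c["x"], c["y"]
            return (y - 0.13 * x**2 + 1.6 * x - 6) ** 2 + 9 * np.cos(x) + 10

        space = SearchSpace(nodes={"x": Uniform(-5, 10), "y": Uniform(0, 15)})
        tpe_best, rs_best = [], []
        for s in range(20):
            b, _ = optimize(branin_like, space, 100, seed=s)
            r, _ = random_search(branin_like, space, 100, seed=s)
            tpe_best.append(b.loss)
            rs_best.append(r.loss)
        assert np.median(tpe_best) <= np.median(rs_best)

    def test_failed_trials_recorded_as_inf(self):
        space = SearchSpace(nodes={"x": Uniform(0, 1)})

        def sometimes_bad(c):
            if c["x"] < 0.5:
                raise ValueError("boom")
            return c["x"]

        with pytest.warns(UserWarning, match="failed"):
            best, hist = optimize(sometimes_bad, space, 30, seed=1)
        assert len(hist) == 30
        assert any(np.isinf(t.loss) for t in hist)
        assert best.loss >= 0.5 and np.isfinite(best.loss)

    def test_best_is_argmin_of_history(self):
        space = krr_search_space(10)
        rng = np.random.default_rng(8)
        for runner in (
            lambda: optimize(lambda c: c["alpha"], space, 25, seed=2),
            lambda: random_search(lambda c: c["alpha"], space, 25, seed=2),
        ):
            best, hist = runner()
            assert best.loss == min(t.loss for t in hist)
            assert all(space.validate(t.config) for t in hist)


class TestRandomSearch:
    def test_deterministic_and_history_independent(self):
        space = krr_search_space(15)
        _, h1 = random_search(lambda c: c["alpha"], space, 20, seed=5)
        _, h2 = random_search(lambda c: -c["alpha"], space, 20, seed=5)
        # different losses, but the sampled configs are identical draws
        assert [t.config for t in h1] == [t.config for t in h2]

    def test_hit_probability_matches_geometric_formula(self):
        space = SearchSpace(nodes={"x": Uniform(0, 1)})
        hits = 0
        for s in range(400):
            best, _ = random_search(
                lambda c: 0.0 if c["x"] < 0.2 else 1.0, space, 10, seed=s
            )
            hits += best.loss == 0.0
        assert hits / 400 == pytest.approx(1 - 0.8**10, abs=0.05)


class TestGridSearch:
    def test_conditional_product_count(self):
        space = krr_search_space(40)
        best, hist = grid_search(lambda c: 0.0, space, default_krr_grid(40))
        assert len(hist) == 120  # (1 + 1 + 4) kernels×gamma x 5 alpha x 4 k

    def test_singleton_grid(self):
        space = SearchSpace(nodes={"x": Uniform(0, 1)})
        _, hist = grid_search(lambda c: c["x"], space, {"x": [0.4]})
        assert len(hist) == 1

    def test_best_not_worse_than_any_point(self):
        space = krr_search_space(10)
        rng = np.random.default_rng(9)
        table = {}

        def obj(c):
            key = tuple(sorted(c.items()))
            table.setdefault(key, float(rng.uniform()))
            return table[key]

        best, hist = grid_search(obj, space, default_krr_grid(10))
        assert all(best.loss <= t.loss for t in hist)

    def test_out_of_bounds_grid_value_rejected(self):
        space = SearchSpace(nodes={"x": Uniform(0, 1)})
        with pytest.raises(ConfigError):
            grid_search(lambda c: 0.0, space, {"x": [2.0]})
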