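"""Predictor correctness: KRR, SVR (SMO), GBLUP/REML and the GRM."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.optimize import minimize

from gptk.errors import ConfigError, NumericalError
from gptk.kernels import KernelSpec
from gptk.models import (
    GBLUPModel,
    fit_gblup,
    fit_krr,
    fit_svr,
    fit_vanraden,
    load_model,
    predict_gblup,
    predict_krr,
    predict_svr,
    save_model,
    vanraden_cross,
    vanraden_grm,
)
from gptk.simulate import SimConfig, simulate_genotypes, simulate_phenotypes


class TestKrr:
    def test_scalar_solve(self):
        m = fit_krr(np.array([[1.0]]), np.array([2.0]), KernelSpec("linear"), alpha=1.0)
        assert m.dual_weights[0] == pytest.approx(1.0)  # 2 / (1 + 1)
        assert predict_krr(m, np.array([[1.0]]))[0] == pytest.approx(1.0)

    def test_equals_primal_ridge_on_random_problems(self, rng):
        for _ in range(50):
            X = rng.normal(size=(20, 5))
            y = rng.normal(size=20)
            alpha = float(rng.uniform(0.01, 5.0))
            m = fit_krr(X, y, KernelSpec("linear"), alpha)
            primal = X @ np.linalg.solve(X.T @ X + alpha * np.eye(5), X.T @ y)
            np.testing.assert_allclose(predict_krr(m, X), primal, atol=1e-8)

    def test_interpolates_at_vanishing_alpha(self, rng):
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        m = fit_krr(X, y, KernelSpec("rbf", gamma=0.5), alpha=1e-10)
        np.testing.assert_allclose(predict_krr(m, X), y, atol=1e-6)

    def test_duplicate_training_row_recovered(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        m = fit_krr(X, y, KernelSpec("rbf", gamma=0.3), alpha=1e-6)
        assert predict_krr(m, X[4:5])[0] == pytest.approx(y[4], abs=1e-3)

    def test_zero_response_zero_prediction(self, rng):
        X = rng.normal(size=(8, 3))
        m = fit_krr(X, np.zeros(8), KernelSpec("rbf", gamma=1.0), alpha=0.1)
        np.testing.assert_allclose(predict_krr(m, rng.normal(size=(5, 3))), 0.0)

    def test_singular_kernel_without_ridge_raises(self):
        X = np.ones((4, 2))  # rank-1 linear kernel
        with pytest.raises(NumericalError, match="alpha"):
            fit_krr(X, np.arange(4.0), KernelSpec("linear"), alpha=0.0)


def _qp_oracle(K, y, C, epsilon):
    """Dense solve of the ε-SVR dual via SLSQP on the stacked variables."""
    n = y.size

    def objective(a):
        beta = a[:n] - a[n:]
        return 0.5 * beta @ K @ beta - y @ beta + epsilon * a.sum()

    def grad(a):
        beta = a[:n] - a[n:]
        g = K @ beta
        return np.concatenate([g - y + epsilon, -g + y + epsilon])

    cons = {"type": "eq", "fun": lambda a: a[:n].sum() - a[n:].sum()}
    res = minimize(
        objective, x0=np.full(2 * n, C / 4), jac=grad, method="SLSQP",
        bounds=[(0, C)] * 2 * n, constraints=[cons],
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    assert res.success
    beta = res.x[:n] - res.x[n:]
    # intercept from free support vectors of either sign
    free_up = (res.x[:n] > 1e-6 * C) & (res.x[:n] < C * (1 - 1e-6))
    free_dn = (res.x[n:] > 1e-6 * C) & (res.x[n:] < C * (1 - 1e-6))
    fitted = K @ beta
    bs = np.concatenate([(y - fitted - epsilon)[free_up], (y - fitted + epsilon)[free_dn]])
    b = float(bs.mean()) if bs.size else 0.0
    return beta, b, res.fun


class TestSvr:
    def test_constant_response_inside_tube(self):
        X = np.arange(6.0)[:, None]
        m = fit_svr(X, np.full(6, 3.3), KernelSpec("linear"), C=5.0, epsilon=0.5)
        np.testing.assert_allclose(m.dual_coefs, 0.0)
        assert m.intercept == pytest.approx(3.3)
        np.testing.assert_allclose(predict_svr(m, X), 3.3)

    def test_toy_problem_matches_qp_oracle(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0], [4.0], [5.0]])
        y = np.array([0.1, 1.2, 1.8, 3.3, 3.9, 5.2])
        spec = KernelSpec("rbf", gamma=0.4)
        from gptk.kernels import compute_kernel

        K = compute_kernel(X, X, spec)
        beta_ref, b_ref, obj_ref = _qp_oracle(K, y, C=2.0, epsilon=0.2)
        m = fit_svr(X, y, spec, C=2.0, epsilon=0.2, tol=1e-8, max_iter=200_000)
        assert m.dual_objective == pytest.approx(obj_ref, abs=1e-4)
        grid = np.linspace(-1, 6, 30)[:, None]
        ref_pred = compute_kernel(grid, X, spec) @ beta_ref + b_ref
        np.testing.assert_allclose(predict_svr(m, grid), ref_pred, atol=1e-4)

    def test_box_constraint_respected(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 15))
            X = rng.normal(size=(n, 2))
            y = rng.normal(size=n)
            C = float(rng.uniform(0.1, 20))
            m = fit_svr(X, y, KernelSpec("rbf", gamma=0.5), C=C, epsilon=0.1,
                        max_iter=100_000)
            assert np.all(np.abs(m.dual_coefs) <= C + 1e-8)

    def test_linear_kernel_equals_explicit_weights(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        m = fit_svr(X, y, KernelSpec("linear"), C=3.0, epsilon=0.1, tol=1e-8,
                    max_iter=200_000)
        w = m.dual_coefs @ X  # β̂ materialized
        Xnew = rng.normal(size=(6, 3))
        np.testing.assert_allclose(
            predict_svr(m, Xnew), Xnew @ w + m.intercept, atol=1e-8
        )

    def test_agrees_with_reference_implementation(self, rng):
        sklearn = pytest.importorskip("sklearn.svm")
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        m = fit_svr(X, y, KernelSpec("rbf", gamma=0.3), C=5.0, epsilon=0.1,
                    tol=1e-7, max_iter=500_000)
        sk = sklearn.SVR(kernel="rbf", gamma=0.3, C=5.0, epsilon=0.1, tol=1e-7).fit(X, y)
        np.testing.assert_allclose(predict_svr(m, X), sk.predict(X), atol=1e-3)

    def test_invalid_parameters(self):
        X, y = np.zeros((3, 1)), np.zeros(3)
        with pytest.raises(ConfigError):
            fit_svr(X, y, KernelSpec("linear"), C=0.0)
        with pytest.raises(ConfigError):
            fit_svr(X, y, KernelSpec("linear"), C=1.0, epsilon=-0.1)


class TestGrm:
    def test_hand_example(self):
        # one marker, dosages (0, 2): p = 0.5, Z = (−1, 1), denominator 0.5
        G = vanraden_grm(np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(G, [[2.0, -2.0], [-2.0, 2.0]], atol=1e-12)

    def test_identical_genotypes_identical_rows(self, rng):
        d = rng.integers(0, 3, size=(5, 40)).astype(float)
        d[1] = d[0]
        G = vanraden_grm(d)
        np.testing.assert_allclose(G[0], G[1], atol=1e-12)
        assert G[0, 0] == pytest.approx(G[0, 1])

    def test_mean_diagonal_near_one_under_hwe(self):
        cfg = SimConfig(n_individuals=500, n_markers=5000, n_qtl=10, n_reference=400,
                        seed=8)
        g = simulate_genotypes(cfg)
        G = vanraden_grm(g.dosages)
        assert np.mean(np.diag(G)) == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_panel_rejected(self):
        with pytest.raises(NumericalError):
            vanraden_grm(np.zeros((4, 3)))


class TestGblup:
    @pytest.fixture(scope="class")
    def panel(self):
        cfg = SimConfig(n_individuals=500, n_markers=1000, n_qtl=60,
                        heritability=0.5, n_reference=400, seed=9)
        g = simulate_genotypes(cfg)
        G = vanraden_grm(g.dosages)
        d, U = np.linalg.eigh(G)
        return cfg, g, G, (d, U)

    def test_null_trait_gets_low_h2(self):
        # m comparable to n keeps enough relationship structure for the null
        # model to be well identified under independent loci
        cfg = SimConfig(n_individuals=500, n_markers=500, n_qtl=60,
                        heritability=0.5, n_reference=400, seed=9)
        G = vanraden_grm(simulate_genotypes(cfg).dosages)
        eig = np.linalg.eigh(G)
        rng = np.random.default_rng(0)
        low = sum(
            fit_gblup(rng.standard_normal(500), G, eig=eig).h2 < 0.1
            for _ in range(50)
        )
        assert low >= 45  # ≥90% of seeds

    def test_h2_recovery(self, panel):
        cfg, g, G, eig = panel
        ests = []
        for s in range(100):
            _, truth = simulate_phenotypes(g, replace(cfg, seed=500 + s))
            y, truth = simulate_phenotypes(g, replace(cfg, seed=500 + s))
            ests.append(fit_gblup(y.values("trait"), G, eig=eig).h2)
        assert np.mean(ests) == pytest.approx(0.5, abs=0.05)

    def test_equivalent_to_krr_with_grm_kernel(self, panel):
        cfg, g, G, eig = panel
        y, _ = simulate_phenotypes(g, cfg)
        model = fit_gblup(y.values("trait"), G, eig=eig)
        yc = y.values("trait") - model.mu
        d, U = eig
        features = U * np.sqrt(np.clip(d, 0, None))  # XXᵀ = G
        krr = fit_krr(features, yc, KernelSpec("linear"), alpha=model.lam)
        np.testing.assert_allclose(predict_krr(krr, features), model.gebv, atol=1e-8)

    def test_training_set_prediction_reproduces_gebv(self, panel):
        cfg, g, G, eig = panel
        y, _ = simulate_phenotypes(g, cfg)
        model = fit_gblup(y.values("trait"), G, eig=eig)
        np.testing.assert_allclose(
            predict_gblup(model, G), model.mu + model.gebv, atol=1e-8
        )

    def test_duplicated_individual_prediction(self, panel):
        cfg, g, G, eig = panel
        y, _ = simulate_phenotypes(g, cfg)
        Gt, st = fit_vanraden(g.dosages)
        model = fit_gblup(y.values("trait"), Gt)
        j = 17
        cross = vanraden_cross(g.dosages[j : j + 1], g.dosages, st)
        assert predict_gblup(model, cross)[0] == pytest.approx(
            model.mu + model.gebv[j], abs=1e-8
        )

    def test_zero_genetic_variance_predicts_mean(self):
        model = GBLUPModel(0.0, 1.0, 1e6, np.eye(3), np.zeros(3), 4.2, np.zeros(3))
        np.testing.assert_allclose(predict_gblup(model, np.eye(3)), 4.2)

    def test_non_psd_grm_rejected(self):
        G = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, −1
        with pytest.raises(NumericalError, match="PSD"):
            fit_gblup(np.zeros(2), G)


class TestInvariances:
    def test_training_order_permutation(self, rng):
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        Xnew = rng.normal(size=(10, 6))
        perm = rng.permutation(40)
        spec = KernelSpec("rbf", gamma=0.2)

        k1 = predict_krr(fit_krr(X, y, spec, 0.5), Xnew)
        k2 = predict_krr(fit_krr(X[perm], y[perm], spec, 0.5), Xnew)
        np.testing.assert_allclose(k1, k2, atol=1e-8)

        s1 = predict_svr(fit_svr(X, y, spec, C=2.0, tol=1e-9, max_iter=500_000), Xnew)
        s2 = predict_svr(
            fit_svr(X[perm], y[perm], spec, C=2.0, tol=1e-9, max_iter=500_000), Xnew
        )
        np.testing.assert_allclose(s1, s2, atol=1e-6)

        G, st = fit_vanraden(X + 1.0)  # shift into a dosage-like positive range
        m1 = fit_gblup(y, G)
        Gp = G[np.ix_(perm, perm)]
        m2 = fit_gblup(y[perm], Gp)
        np.testing.assert_allclose(m1.gebv[perm], m2.gebv, atol=1e-8)


class TestSerialization:
    def test_round_trip_all_kinds(self, tmp_path, rng):
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        models = {
            "krr": fit_krr(X, y, KernelSpec("rbf", gamma=0.5), 0.3),
            "svr": fit_svr(X, y, KernelSpec("linear"), C=2.0),
        }
        G = vanraden_grm(rng.integers(0, 3, size=(20, 50)).astype(float))
        models["gblup"] = fit_gblup(y, G)
        Xnew = rng.normal(size=(5, 4))
        preds = {
            "krr": predict_krr(models["krr"], Xnew),
            "svr": predict_svr(models["svr"], Xnew),
            "gblup": predict_gblup(models["gblup"], G[:5]),
        }
        for kind, model in models.items():
            path = tmp_path / f"{kind}.npz"
            save_model(model, path)
            loaded = load_model(path)
            if kind == "krr":
                again = predict_krr(loaded, Xnew)
            elif kind == "svr":
                again = predict_svr(loaded, Xnew)
            else:
                again = predict_gblup(loaded, G[:5])
            np.testing.assert_allclose(again, preds[kind], atol=1e-12)
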