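"""KRR and Adaboost.RT: closed-form equivalences, hand-traced boosting
updates, and committee properties."""

import numpy as np
import pytest

from caprigen import (
    KernelSpec,
    RelationshipMatrix,
    VarianceComponents,
    adaboost_rt_fit,
    adaboost_rt_predict,
    gblup_predict,
    kernel_grid_search,
    krr_fit,
    relationship_features,
)
from caprigen.ensemble import committee_training_error

from .conftest import phenotypes_from_values


class TestKRR:
    def test_interpolation_with_orthonormal_features(self):
        y = np.array([1.0, -2.0, 3.0, 0.5])
        model = krr_fit(np.eye(4), y, "linear", alpha=0.0)
        assert np.allclose(model.predict(np.eye(4)), y, atol=1e-10)

    def test_total_shrinkage_at_large_alpha(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        model = krr_fit(x, y, "linear", alpha=1e12)
        assert np.all(np.abs(model.predict(x)) < 1e-6)

    def test_linear_kernel_matches_primal_ridge_oracle(self):
        """Dual KRR with a linear kernel equals primal ridge regression."""
        rng = np.random.default_rng(1)
        x = rng.standard_normal((30, 4))
        x -= x.mean(axis=0)
        y = rng.standard_normal(30)
        alpha = 0.7
        model = krr_fit(x, y, "linear", alpha=alpha)
        # primal: beta = (X'X + alpha I)^-1 X'y
        beta = np.linalg.solve(x.T @ x + alpha * np.eye(4), x.T @ y)
        xq = rng.standard_normal((10, 4))
        assert np.allclose(model.predict(xq), xq @ beta, atol=1e-8)

    def test_dual_coefficients_solve_the_system(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((15, 3))
        y = rng.standard_normal(15)
        model = krr_fit(x, y, KernelSpec("rbf", gamma=0.5), alpha=1.0)
        K = model.kernel_spec.gram(x)
        resid = (K + np.eye(15)) @ model.dual_coefficients - y
        assert np.max(np.abs(resid)) < 1e-8

    def test_krr_precomputed_equals_gblup_training_blups(self):
        """K = G_train with ridge sigma_e^2/sigma_g^2 reproduces GBLUP
        breeding values on centered phenotypes."""
        rng = np.random.default_rng(3)
        n = 40
        w = rng.standard_normal((n, 2 * n))
        G = RelationshipMatrix([f"s{i}" for i in range(n)],
                               0.95 * (w @ w.T) / (2 * n) + 0.05 * np.eye(n), 1.0)
        y = rng.standard_normal(n)
        y -= y.mean()
        sg2, se2 = 1.3, 2.1
        lam = se2 / sg2
        krr = krr_fit(G.values, y, "precomputed", alpha=lam)
        krr_train_pred = krr.predict(G.values)
        vc = VarianceComponents(["trait0"], [[sg2]], [[se2]])
        phenos = phenotypes_from_values(y)
        gblup = gblup_predict(phenos, G, vc, list(G.sample_ids), trait=0,
                              fixed_effects=False)
        assert np.allclose(krr_train_pred, gblup, atol=1e-6)


class TestKernelGridSearch:
    def test_single_element_grid_returned(self):
        x = np.random.default_rng(0).standard_normal((30, 2))
        spec = kernel_grid_search(x, x[:, 0], [KernelSpec("linear")], seed=0)
        assert spec.name == "linear"

    def test_constant_target_falls_back_to_first_element(self):
        x = np.random.default_rng(0).standard_normal((30, 2))
        grid = [KernelSpec("rbf", gamma=1.0), KernelSpec("linear")]
        spec = kernel_grid_search(x, np.ones(30), grid, seed=0)
        assert spec is grid[0]

    def test_radial_data_selects_radial_kernel(self):
        """A smooth radial target should beat the linear kernel in >= 80%
        of seeded replicates."""
        grid = [KernelSpec("linear"), KernelSpec("rbf", gamma=1.0)]
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.uniform(-2, 2, size=(80, 2))
            y = np.exp(-np.sum(x**2, axis=1)) + 0.05 * rng.standard_normal(80)
            if kernel_grid_search(x, y, grid, seed=seed).name == "rbf":
                wins += 1
        assert wins >= 8

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            kernel_grid_search(np.eye(20), np.arange(20.0), [])


def _stub_factory(outputs):
    """Weak learner that always predicts the same fixed vector."""
    outputs = np.asarray(outputs, dtype=float)

    class Stub:
        def predict(self, x):
            return outputs[: len(x)]

    def factory(x, y, rng):
        return Stub()

    return factory


class TestAdaboostRT:
    def test_hand_traced_updates(self):
        """Two rounds on a 3-sample toy with a constant stub learner.

        y = (1, 2, 4), predictions always (1, 1, 1), phi = 0.5:
        ARE = (0, 0.5, 0.75) so only sample 3 is mis-predicted.
        Round 1: eps = 1/3, D2 = (0.2, 0.2, 0.6).
        Round 2: eps = 0.6,  D3 = (1/7, 1/7, 5/7).
        """
        y = np.array([1.0, 2.0, 4.0])
        x = np.zeros((3, 1))
        ens = adaboost_rt_fit(x, y, n_estimators=2, phi=0.5, seed=0,
                              base_learner=_stub_factory([1.0, 1.0, 1.0]))
        assert ens.error_rates[0] == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert ens.error_rates[1] == pytest.approx(0.6, abs=1e-12)
        assert np.allclose(ens.distribution_, [1 / 7, 1 / 7, 5 / 7], atol=1e-12)
        assert np.allclose(adaboost_rt_predict(ens, x), 1.0)

    def test_distribution_always_normalized(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((40, 3))
        y = x[:, 0] + 0.3 * rng.standard_normal(40)
        ens = adaboost_rt_fit(x, y, n_estimators=30, phi=0.2, seed=1)
        assert ens.distribution_.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.array(ens.error_rates) > 0)
        assert np.all(np.array(ens.error_rates) < 1)

    def test_single_estimator_equals_weak_learner(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((25, 2))
        y = x[:, 0] ** 2
        ens = adaboost_rt_fit(x, y, n_estimators=1, phi=0.1, seed=2)
        assert np.allclose(ens.predict(x), ens.learners[0].predict(x))

    def test_prediction_is_convex_combination(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((30, 2))
        y = np.sin(x[:, 0]) + 0.1 * rng.standard_normal(30)
        ens = adaboost_rt_fit(x, y, n_estimators=20, phi=0.3, seed=3)
        preds = np.stack([l.predict(x) for l in ens.learners])
        committee = ens.predict(x)
        assert np.all(committee <= preds.max(axis=0) + 1e-10)
        assert np.all(committee >= preds.min(axis=0) - 1e-10)

    @pytest.mark.parametrize("outputs,eps,expected", [
        ([1.0, 3.0], [np.exp(-1), np.exp(-1)], 2.0),       # equal weights
        ([0.0, 3.0], [np.exp(-2), np.exp(-1)], 1.0),       # weights 2:1
    ])
    def test_weighted_committee_combinations(self, outputs, eps, expected):
        from caprigen import BoostEnsemble

        class Const:
            def __init__(self, c):
                self.c = c

            def predict(self, x):
                return np.full(len(x), self.c)

        ens = BoostEnsemble(learners=[Const(c) for c in outputs],
                            error_rates=list(eps), phi=0.5)
        assert adaboost_rt_predict(ens, np.zeros((4, 1)))[0] == pytest.approx(expected)

    def test_training_error_non_increasing_in_rounds(self):
        """On a noise-free smooth target, adding committee members does not
        make the thresholded training error worse."""
        rng = np.random.default_rng(0)
        x = rng.uniform(-2, 2, size=(120, 2))
        y = np.sin(2 * x[:, 0])
        errs = [
            committee_training_error(
                adaboost_rt_fit(x, y, n_estimators=m, phi=0.5, seed=8), x, y)
            for m in (1, 5, 50)
        ]
        assert errs[1] <= errs[0] + 0.05
        assert errs[2] <= errs[0] + 0.05

    def test_invalid_inputs_rejected(self):
        x = np.zeros((20, 2))
        with pytest.raises(ValueError):
            adaboost_rt_fit(x, np.ones(20), n_estimators=5, phi=0.1)
        with pytest.raises(ValueError):
            adaboost_rt_fit(x, np.arange(20.0), n_estimators=5, phi=-1.0)
        from caprigen import BoostEnsemble
        with pytest.raises(ValueError):
            adaboost_rt_predict(BoostEnsemble(), x)


class TestModelSerialization:
    def test_krr_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((20, 4))
        y = rng.standard_normal(20)
        model = krr_fit(x, y, KernelSpec("rbf", gamma=0.3), alpha=0.5)
        from caprigen import load_model, save_model
        p = tmp_path / "krr.json"
        save_model(model, p)
        loaded = load_model(p)
        xq = rng.standard_normal((7, 4))
        assert np.allclose(loaded.predict(xq), model.predict(xq), atol=1e-12)

    def test_adaboost_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((30, 3))
        y = x[:, 0] + 0.2 * rng.standard_normal(30)
        ens = adaboost_rt_fit(x, y, n_estimators=8, phi=0.3, seed=4)
        from caprigen import load_model, save_model
        p = tmp_path / "boost.json"
        save_model(ens, p)
        loaded = load_model(p)
        xq = rng.standard_normal((9, 3))
        assert np.allclose(loaded.predict(xq), ens.predict(xq), atol=1e-10)
        assert loaded.error_rates == pytest.approx(ens.error_rates)


class TestRelationshipFeatures:
    def _g(self):
        vals = np.array([[1.0, 0.2, -0.1],
                         [0.2, 1.1, 0.4],
                         [-0.1, 0.4, 0.9]])
        return RelationshipMatrix(["a", "b", "c"], vals, 1.0)

    def test_rows_match_matrix_slices(self):
        G = self._g()
        feats = relationship_features(G, ["a", "c"], ["b"])
        assert np.allclose(feats, [[0.2, 0.4]])

    def test_query_in_training_sees_own_diagonal(self):
        G = self._g()
        feats = relationship_features(G, ["a", "b", "c"], ["b"])
        assert feats[0, 1] == pytest.approx(1.1)

    def test_identity_g_unrelated_query_is_zero(self):
        G = RelationshipMatrix(["a", "b", "c"], np.eye(3), 1.0)
        assert np.allclose(relationship_features(G, ["a", "b"], ["c"]), 0.0)

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError):
            relationship_features(self._g(), ["a"], ["zz"])
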