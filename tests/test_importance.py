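import numpy as np
import pandas as pd
import pytest

from sedmoc.importance import (importance_with_ci, nash_sutcliffe,
                               partial_derivative_sensitivity,
                               process_importance, train_emulator)

PROCS = ["DOC hydrolysis", "remineralization", "mixing",
         "equilibrium adsorption", "kinetic sorption", "geopolymerization"]


def _linear_table(rng, n=300, n_feat=4, noise=1e-3):
    X = pd.DataFrame(rng.uniform(-1, 1, (n, n_feat)),
                     columns=[f"x{i}" for i in range(n_feat)])
    y = 3.0 * X["x0"].to_numpy() + noise * rng.normal(size=n)
    return X, y


class TestEmulator:
    def test_linear_recovery(self, rng):
        X, y = _linear_table(rng)
        em = train_emulator(X, y, seed=0)
        assert em.nse > 0.999
        sens = partial_derivative_sensitivity(em, X)
        assert sens["x0"] > 10 * max(sens["x1"], sens["x2"], sens["x3"])

    def test_no_signal_no_skill(self, rng):
        X = pd.DataFrame(rng.uniform(0, 1, (200, 3)), columns=list("abc"))
        y = rng.normal(size=200)
        em = train_emulator(X, y, seed=1)
        assert em.nse < 0.05  # held-out efficiency of a noise fit

    def test_degenerate_target_rejected(self, rng):
        X = pd.DataFrame(rng.uniform(0, 1, (50, 2)), columns=list("ab"))
        with pytest.raises(ValueError):
            train_emulator(X, np.ones(50), seed=0)

    def test_nash_sutcliffe_definition(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert nash_sutcliffe(obs, obs) == 1.0
        assert nash_sutcliffe(obs, np.full(3, obs.mean())) == pytest.approx(0.0)


class TestPartialDerivatives:
    def test_matches_finite_differences(self, rng):
        X, y = _linear_table(rng, n=250)
        # give the target curvature so the network is genuinely nonlinear
        y = y + 0.5 * X["x1"].to_numpy() ** 2
        em = train_emulator(X, y, seed=2)
        Xs = em.standardize(X)
        mlp = em.mlp
        h = 1e-6
        grads_fd = np.zeros_like(Xs)
        for k in range(Xs.shape[1]):
            up, dn = Xs.copy(), Xs.copy()
            up[:, k] += h
            dn[:, k] -= h
            grads_fd[:, k] = (mlp.predict(up) - mlp.predict(dn)) / (2 * h)
        W1, w2 = mlp.coefs_
        hidden = np.tanh(Xs @ W1 + mlp.intercepts_[0])
        grads = ((1 - hidden ** 2) * w2.ravel()) @ W1.T
        np.testing.assert_allclose(grads, grads_fd, rtol=1e-6, atol=1e-9)

    def test_zeroed_input_gets_zero_score(self, rng):
        X, y = _linear_table(rng)
        em = train_emulator(X, y, seed=3)
        em.mlp.coefs_[0][2, :] = 0.0  # sever all paths from x2
        sens = partial_derivative_sensitivity(em, X)
        assert sens["x2"] == 0.0

    def test_untrained_network_rejected(self, rng):
        from sklearn.neural_network import MLPRegressor
        from sedmoc.importance import Emulator
        X, _ = _linear_table(rng, n=20)
        em = Emulator(mlp=MLPRegressor(), feature_names=list(X.columns),
                      transforms={}, x_mean=np.zeros(4), x_std=np.ones(4),
                      y_mean=0.0, y_std=1.0, nse=0.0, hidden_size=4)
        with pytest.raises(ValueError):
            partial_derivative_sensitivity(em, X)


class TestProcessImportance:
    def test_equal_sensitivities_uniform_split(self):
        sens = pd.Series(1.0, index=[f"p{i}" for i in range(6)])
        grouping = {f"p{i}": PROCS[i] for i in range(6)}
        imp = process_importance(sens, grouping)
        np.testing.assert_allclose(imp.to_numpy(), 100.0 / 6.0, rtol=1e-12)

    def test_dominated_member_ignored_by_max(self):
        grouping = {"a": PROCS[0], "a2": PROCS[0], "b": PROCS[1]}
        imp1 = process_importance(pd.Series({"a": 2.0, "b": 1.0}),
                                  {"a": PROCS[0], "b": PROCS[1]})
        imp2 = process_importance(pd.Series({"a": 2.0, "a2": 0.5, "b": 1.0}),
                                  grouping)
        np.testing.assert_allclose(imp1.to_numpy(), imp2.to_numpy(), rtol=1e-12)

    def test_sum_always_100(self, rng):
        names = [f"p{i}" for i in range(12)]
        grouping = {nm: PROCS[i % 6] for i, nm in enumerate(names)}
        for _ in range(10):
            sens = pd.Series(rng.uniform(0.01, 5.0, 12), index=names)
            assert process_importance(sens, grouping).sum() == pytest.approx(100.0)

    def test_ungrouped_parameter_rejected(self):
        with pytest.raises(KeyError):
            process_importance(pd.Series({"a": 1.0}), {})


class TestImportanceWithCI:
    def _synthetic(self, rng, n=250):
        names = [f"p{i}" for i in range(6)]
        grouping = {nm: PROCS[i] for i, nm in enumerate(names)}
        X = pd.DataFrame(rng.uniform(0, 1, (n, 6)), columns=names)
        # the output is driven solely by the kinetic-sorption parameter p4
        y = np.sin(2.0 * X["p4"].to_numpy()) + 0.01 * rng.normal(size=n)
        return X, y, grouping

    def test_single_driver_dominates(self, rng):
        X, y, grouping = self._synthetic(rng)
        res = importance_with_ci(X, y, grouping, n_repeats=5, seed=0)
        top = res.ranked().iloc[0]
        assert top["process"] == "kinetic sorption"
        assert top["mean"] > 80.0

    def test_reproducible_under_fixed_seed(self, rng):
        X, y, grouping = self._synthetic(rng, n=150)
        r1 = importance_with_ci(X, y, grouping, n_repeats=3, seed=5)
        r2 = importance_with_ci(X, y, grouping, n_repeats=3, seed=5)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_mean_importances_sum_to_100(self, rng):
        X, y, grouping = self._synthetic(rng, n=150)
        res = importance_with_ci(X, y, grouping, n_repeats=4, seed=2)
        assert res.table["mean"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_scale_invariance_of_inputs(self, rng):
        """Sensitivities are taken on standardized inputs, so a pure
        rescaling of a raw input column must not change them."""
        from dataclasses import replace
        X, y, grouping = self._synthetic(rng, n=200)
        em = train_emulator(X, y, seed=8)
        sens1 = partial_derivative_sensitivity(em, X)
        X2 = X.copy()
        X2["p2"] = X2["p2"] * 1000.0
        mean2, std2 = em.x_mean.copy(), em.x_std.copy()
        k = list(X.columns).index("p2")
        mean2[k] *= 1000.0
        std2[k] *= 1000.0
        em2 = replace(em, x_mean=mean2, x_std=std2)
        sens2 = partial_derivative_sensitivity(em2, X2)
        np.testing.assert_allclose(sens1, sens2, rtol=1e-9)
        imp1 = process_importance(sens1, grouping)
        imp2 = process_importance(sens2, grouping)
        np.testing.assert_allclose(imp1, imp2, rtol=1e-9)

    def test_parameter_order_invariance(self, rng):
        names = [f"p{i}" for i in range(8)]
        grouping = {nm: PROCS[i % 6] for i, nm in enumerate(names)}
        sens = pd.Series(rng.uniform(0.1, 3.0, 8), index=names)
        perm = rng.permutation(8)
        imp1 = process_importance(sens, grouping).sort_index()
        imp2 = process_importance(sens.iloc[perm], grouping).sort_index()
        np.testing.assert_allclose(imp1, imp2, rtol=1e-12)

    def test_too_few_repeats_rejected(self, rng):
        X, y, grouping = self._synthetic(rng, n=100)
        with pytest.raises(ValueError):
            importance_with_ci(X, y, grouping, n_repeats=1, seed=0)
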