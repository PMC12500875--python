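"""Monomial model, feedforward network, and ensemble regressor contracts."""

import numpy as np
import pandas as pd
import pytest

from enviropinet.dimensions import evaluate_pi
from enviropinet.evaluation import r_squared
from enviropinet.models import (
    EnsembleConfig,
    FFNNConfig,
    MonomialModel,
    back_transform,
    fit_monomial,
    predict_monomial,
    train_ensemble,
    train_ffnn,
)
from enviropinet.synthetic import DEFAULT_BETA, DEFAULT_BETA0, SyntheticConfig, generate

PAPER_MODEL = MonomialModel(
    beta0=-0.07,
    exponents={"Pz/C_fit": -0.06, "Bt/A": -0.30, "P/C_fit": 0.53, "t0/T": -0.09},
)


class TestMonomial:
    def test_exact_recovery_on_noiseless_data(self, table_clean, basis):
        pi = evaluate_pi(basis, table_clean)
        m = fit_monomial(pi[basis.labels], pi[basis.dependent.label])
        assert m.beta0 == pytest.approx(DEFAULT_BETA0, abs=1e-10)
        for b, (_, est) in zip(DEFAULT_BETA, m.exponents.items()):
            assert est == pytest.approx(b, abs=1e-10)

    def test_generating_law_reproduced_at_fresh_points(self, table_clean, basis):
        pi = evaluate_pi(basis, table_clean)
        m = fit_monomial(pi[basis.labels].iloc[:200], pi[basis.dependent.label].iloc[:200])
        fresh = generate(SyntheticConfig(sigma=0.0, seed=77))
        pi_f = evaluate_pi(basis, fresh)
        pred = predict_monomial(m, pi_f[basis.labels])
        assert np.allclose(pred, pi_f[basis.dependent.label], rtol=1e-8)

    def test_constant_dependent_gives_zero_exponents(self, table_clean, basis):
        pi = evaluate_pi(basis, table_clean)
        m = fit_monomial(pi[basis.labels], np.full(len(pi), 0.42))
        assert m.beta0 == pytest.approx(np.log(0.42), abs=1e-10)
        assert all(abs(b) < 1e-10 for b in m.exponents.values())

    def test_collinear_columns_named(self, table_clean, basis):
        pi = evaluate_pi(basis, table_clean)
        x = pi[basis.labels].copy()
        x["dup"] = x["Bt/A"] ** 2  # log-collinear with Bt/A
        with pytest.raises(ValueError) as err:
            fit_monomial(x, pi[basis.dependent.label])
        assert "Bt/A" in str(err.value) and "dup" in str(err.value)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_monomial(pd.DataFrame({"a": [1.0, -1.0]}), [1.0, 1.0])
        with pytest.raises(ValueError, match="positive"):
            fit_monomial(pd.DataFrame({"a": [1.0, 2.0]}), [1.0, 0.0])

    def test_printed_coefficients_on_all_ones_row(self):
        ones = pd.DataFrame([{k: 1.0 for k in PAPER_MODEL.feature_names}])
        assert predict_monomial(PAPER_MODEL, ones)[0] == pytest.approx(0.93, abs=0.005)

    def test_log_prediction_is_affine_in_log_pi(self):
        rng = np.random.default_rng(8)
        a = pd.DataFrame(
            np.exp(rng.uniform(-1, 1, size=(5, 4))), columns=PAPER_MODEL.feature_names
        )
        lam = 0.37
        b = a**2
        mix = np.exp(lam * np.log(a) + (1 - lam) * np.log(b))
        lhs = np.log(predict_monomial(PAPER_MODEL, mix))
        rhs = lam * np.log(predict_monomial(PAPER_MODEL, a)) + (1 - lam) * np.log(
            predict_monomial(PAPER_MODEL, b)
        )
        assert np.allclose(lhs, rhs, rtol=1e-10)

    def test_recovery_rate_under_noise_matches_sampling_theory(self, basis):
        """Each exponent recovered within a tolerance frozen from the
        closed-form OLS sampling-error oracle (3 standard errors, floored
        at 0.05), in >= 95 of 100 seeded replicates at n=300, sigma=0.05."""
        from enviropinet.harness import monomial_recovery

        n, sigma = 300, 0.05
        ref = generate(SyntheticConfig(n_rows=n, sigma=0.0, study_sizes=None, seed=1))
        pi = evaluate_pi(basis, ref)
        x = np.column_stack([np.ones(n), np.log(pi[basis.labels])])
        se = sigma * np.sqrt(np.diag(np.linalg.inv(x.T @ x)))[1:]
        tol = np.maximum(0.05, 3 * se)
        out = monomial_recovery(n=n, sigma=sigma, replicates=100, tol=tol, seed=2)
        for rate in out["per_exponent_rate"]:
            assert rate >= 0.95


class TestFFNN:
    def test_noiseless_linear_target_learned(self, fast_ffnn):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(200, 4))
        y = x @ np.array([1.0, -2.0, 0.5, 0.0]) + 0.3
        res = train_ffnn(x, y, fast_ffnn)
        probe = rng.normal(size=(60, 4))
        assert r_squared(probe @ np.array([1.0, -2.0, 0.5, 0.0]) + 0.3,
                         res.predict(probe, 0)) >= 0.99

    def test_same_seed_identical_weights_and_traces(self, fast_ffnn):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(80, 4))
        y = x.sum(axis=1)
        a = train_ffnn(x, y, fast_ffnn)
        b = train_ffnn(x, y, fast_ffnn)
        pd.testing.assert_frame_equal(a.traces, b.traces)
        for wa, wb in zip(a.models[0].coefs_, b.models[0].coefs_):
            assert np.array_equal(wa, wb)

    def test_training_reduces_loss(self, fast_ffnn):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(100, 4))
        y = x @ np.array([0.5, 1.0, -1.0, 0.2])
        res = train_ffnn(x, y, fast_ffnn)
        final = res.traces[res.traces["fold"] == -1]
        assert final["train_mse"].iloc[-1] <= final["train_mse"].iloc[0]

    def test_config_validation(self):
        with pytest.raises(ValueError, match="two hidden"):
            FFNNConfig(hidden=(8,))

    def test_traces_cover_all_folds(self, fast_ffnn):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(60, 4))
        res = train_ffnn(x, x.sum(axis=1), fast_ffnn)
        assert set(res.traces["fold"]) == {-1, 0, 1, 2}
        assert {"train_mse", "train_mae", "val_mse", "val_mae"} <= set(res.traces.columns)


class TestEnsembles:
    @pytest.fixture(scope="class")
    def xy(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(150, 4))
        y = x @ np.array([1.0, 0.5, -0.5, 0.2]) + 0.1 * rng.normal(size=150)
        return x, y

    def test_ridge_handles_exact_collinearity(self, xy):
        x, y = xy
        xx = np.hstack([x, x[:, :1]])  # duplicated feature
        model = train_ensemble(xx, y, EnsembleConfig(kind="ridge"))
        assert np.all(np.isfinite(model.coef_))

    @pytest.mark.parametrize("kind", ["gbr", "rfr"])
    def test_tree_models_deterministic_with_seed_42(self, xy, kind):
        x, y = xy
        a = train_ensemble(x, y, EnsembleConfig(kind=kind)).predict(x)
        b = train_ensemble(x, y, EnsembleConfig(kind=kind)).predict(x)
        assert np.array_equal(a, b)

    def test_svr_epsilon_tube_on_constant_target(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(100, 3))
        y = 1.0 + rng.uniform(-0.05, 0.05, size=100)  # inside the 0.1 tube
        model = train_ensemble(x, y, EnsembleConfig(kind="svr"))
        pred = model.predict(x)
        # epsilon-insensitive loss admits a flat fit within the tube
        assert np.all(np.abs(pred - y) <= 0.1 + 1e-6)

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_ensemble(np.empty((5, 0)), np.ones(5), EnsembleConfig(kind="svr"))


class TestBackTransform:
    def test_definition_and_paper_intercept_case(self):
        assert back_transform([0.5], [2.0])[0] == pytest.approx(1.0)
        assert back_transform([0.93], [1.0])[0] == pytest.approx(0.93)

    def test_round_trip(self, table_noisy):
        ec = table_noisy["EC_org"].to_numpy()
        ic = table_noisy["IC_org"].to_numpy()
        assert np.allclose(back_transform(ec / ic, ic), ec, rtol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            back_transform([1.0, 2.0], [1.0])
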