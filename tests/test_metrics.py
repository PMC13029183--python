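"""Validation battery: fit statistics, cross-validation, randomization,
rm2 metrics and leverage applicability domain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sertqsar.metrics import (
    basic_stats,
    ccc,
    friedman_lof,
    iic,
    leverage_ad,
    mae_classify,
    q2_lmo,
    q2_loo,
    rm2_block,
    y_randomization,
)


def _ols_fitter(X, y):
    X = np.asarray(X, dtype=float)
    Xa = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    return lambda Xn: np.column_stack(
        [np.ones(len(np.atleast_2d(Xn))), np.atleast_2d(Xn)]
    ) @ beta


class TestBasicStats:
    def test_identity_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        out = basic_stats(y, y)
        assert out["r2"] == pytest.approx(1.0)
        assert out["ccc"] == pytest.approx(1.0)
        assert out["iic"] == pytest.approx(1.0)
        assert out["rmse"] == 0.0

    def test_location_shift_penalized_by_ccc_not_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        out = basic_stats(y, y + 1.0)
        assert out["r2"] == pytest.approx(1.0)
        assert out["ccc"] < 1.0

    def test_matches_textbook_formulas(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(7, 0.6, 25)
        pred = obs + rng.normal(0, 0.3, 25)
        out = basic_stats(obs, pred)
        r = np.corrcoef(obs, pred)[0, 1]
        assert out["r2"] == pytest.approx(r**2)
        assert out["rmse"] == pytest.approx(np.sqrt(np.mean((obs - pred) ** 2)))
        assert out["mae"] == pytest.approx(np.mean(np.abs(obs - pred)))
        # Lin's CCC, written out long-hand
        sx, sy = obs.var(), pred.var()
        expected_ccc = (
            2 * np.cov(obs, pred, bias=True)[0, 1]
            / (sx + sy + (obs.mean() - pred.mean()) ** 2)
        )
        assert out["ccc"] == pytest.approx(expected_ccc)
        # IIC from the residual-balance definition
        resid = obs - pred
        mae_n = np.abs(resid[resid < 0]).mean()
        mae_p = np.abs(resid[resid >= 0]).mean()
        assert out["iic"] == pytest.approx(r * min(mae_n, mae_p) / max(mae_n, mae_p))

    @given(
        arrays(np.float64, 12, elements=st.floats(-50, 50)),
        arrays(np.float64, 12, elements=st.floats(-50, 50)),
    )
    @settings(max_examples=60, deadline=None)
    def test_ccc_bounded_by_correlation(self, obs, pred):
        if np.var(obs) < 1e-6 or np.var(pred) < 1e-6:
            return
        r = np.corrcoef(obs, pred)[0, 1]
        assert abs(ccc(obs, pred)) <= abs(r) + 1e-9

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            basic_stats([1, 2, 3], [1, 2])


class TestCrossValidation:
    def test_noiseless_linear_data_gives_q2_one(self):
        X = np.arange(10.0).reshape(-1, 1)
        y = 2.0 + 3.0 * X[:, 0]
        assert q2_loo(_ols_fitter, X, y) == pytest.approx(1.0)

    def test_q2_loo_equals_explicit_refit_loop(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 1))
        y = 1.0 + 2.0 * X[:, 0] + rng.normal(0, 0.2, 6)
        press = 0.0
        for i in range(6):
            mask = np.ones(6, bool)
            mask[i] = False
            predict = _ols_fitter(X[mask], y[mask])
            press += (y[i] - predict(X[i : i + 1])[0]) ** 2
        expected = 1 - press / ((y - y.mean()) ** 2).sum()
        assert q2_loo(_ols_fitter, X, y) == pytest.approx(expected)

    def test_lmo_with_singleton_groups_reduces_to_loo(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 1))
        y = 1.0 + 2.0 * X[:, 0] + rng.normal(0, 0.3, 8)
        loo = q2_loo(_ols_fitter, X, y)
        lmo = q2_lmo(_ols_fitter, X, y, leave_fraction=1 / 8, reps=8, seed=0)
        assert lmo == pytest.approx(loo)

    def test_failing_fold_is_named(self):
        def broken(X, y):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="fold 0"):
            q2_loo(broken, np.arange(5.0).reshape(-1, 1), np.arange(5.0))


class TestYRandomization:
    def test_strong_signal_passes(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 1))
        y = 2.0 * X[:, 0] + rng.normal(0, 0.3, 40)
        rep = y_randomization(_ols_fitter, X, y, n_permutations=100, n_runs=1, seed=0)
        assert rep.mean_rr2 < 0.1
        assert rep.passed and rep.crp2 > 0.5

    def test_pure_noise_fails(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 1))
        y = rng.normal(size=40)
        rep = y_randomization(_ols_fitter, X, y, n_permutations=100, n_runs=1, seed=0)
        assert not rep.passed

    def test_zero_mean_rr2_gives_crp2_equal_r2(self):
        # algebraic limit: cRp2 = R*sqrt(R2 - 0) = R2
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 1))
        y = 3.0 * X[:, 0]
        rep = y_randomization(_ols_fitter, X, y, n_permutations=10, n_runs=1, seed=0)
        assert rep.crp2 == pytest.approx(
            np.sqrt(rep.r2) * np.sqrt(rep.r2 - rep.mean_rr2)
        )


class TestRm2:
    def test_identity(self):
        y = np.array([1.0, 2.0, 3.0])
        out = rm2_block(y, y)
        assert out["k"] == pytest.approx(1.0)
        assert out["k_prime"] == pytest.approx(1.0)
        assert out["rm2"] == pytest.approx(1.0)

    def test_scaled_predictions_flip_slopes(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        out = rm2_block(y, 2 * y)
        assert out["k"] == pytest.approx(0.5)
        assert out["k_prime"] == pytest.approx(2.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        obs = rng.normal(7, 0.5, 15)
        pred = obs + rng.normal(0, 0.2, 15)
        out = rm2_block(obs, pred)
        r2 = np.corrcoef(obs, pred)[0, 1] ** 2
        k = (pred * obs).sum() / (pred * pred).sum()
        r2o = 1 - ((obs - k * pred) ** 2).sum() / ((obs - obs.mean()) ** 2).sum()
        assert out["k"] == pytest.approx(k)
        assert out["rm2"] == pytest.approx(r2 * (1 - np.sqrt(r2 - r2o)))


class TestMAEClass:
    def test_perfect_predictions_good(self):
        y = np.array([6.0, 7.0, 8.0])
        assert mae_classify(y, y, train_range=2.0) == "GOOD"

    def test_large_errors_bad(self):
        y = np.array([6.0, 7.0, 8.0])
        assert mae_classify(y, y + 0.8, train_range=2.0) == "BAD"

    def test_class_boundary(self):
        y = np.array([6.0, 6.5, 7.0, 7.5])
        # constant error => residual sd = 0, so only the MAE rule is active
        assert mae_classify(y, y + 0.12, train_range=1.0) == "MODERATE"
        assert mae_classify(y, y + 0.2, train_range=1.0) == "BAD"


class TestLeverageAD:
    def test_reference_threshold(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(38, 5))
        resid = rng.normal(0, 0.2, 38)
        lev = leverage_ad(X, resid)
        assert lev.h_star == pytest.approx(3 * 6 / 38) == pytest.approx(0.4737, abs=1e-4)
        assert lev.h.sum() == pytest.approx(6.0)

    def test_hat_values_match_matrix_algebra(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 2))
        resid = rng.normal(0, 0.1, 10)
        lev = leverage_ad(X, resid)
        Xa = np.column_stack([np.ones(10), X])
        H = Xa @ np.linalg.inv(Xa.T @ Xa) @ Xa.T
        assert lev.h == pytest.approx(np.diag(H))

    def test_rank_deficiency_rejected(self):
        X = np.ones((6, 2))
        with pytest.raises(ValueError):
            leverage_ad(X, np.zeros(6))


def test_friedman_lof_increases_with_parameters():
    resid = np.full(20, 0.5)
    assert friedman_lof(resid, 2, 20) < friedman_lof(resid, 8, 20)
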