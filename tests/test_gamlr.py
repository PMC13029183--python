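"""GA descriptor selection and MLR fitting."""

import numpy as np
import pytest

from sertqsar.gamlr import DescriptorMatrix, GAConfig, fit_mlr, ga_select, preprocess
from sertqsar.simulate import gen_descriptor_matrix


def _matrix(X, names=None):
    n, p = X.shape
    names = names or [f"D{j}" for j in range(p)]
    return DescriptorMatrix(ids=[f"m{i}" for i in range(n)], names=names, X=X)


class TestPreprocess:
    def test_constant_column_removed(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(size=20), np.full(20, 2.0)])
        out = preprocess(_matrix(X, ["a", "const"]))
        assert out.names == ["a"]

    def test_duplicate_column_exactly_one_survives(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=30)
        X = np.column_stack([col, col.copy(), rng.normal(size=30)])
        out = preprocess(_matrix(X, ["a", "a_dup", "b"]))
        assert len([n for n in out.names if n.startswith("a")]) == 1

    def test_retention_prefers_activity_correlated_column(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=40)
        noisy = base + rng.normal(0, 0.05, 40)  # |r| > 0.9 pair
        y = base * 2.0
        X = np.column_stack([noisy, base])
        out = preprocess(_matrix(X, ["noisy", "clean"]), activities=y)
        assert out.names == ["clean"]

    def test_matches_greedy_filter_replay(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 8))
        X[:, 3] = X[:, 1] * 0.99 + rng.normal(0, 0.01, 25)
        y = rng.normal(size=25)
        out = preprocess(_matrix(X), activities=y)
        # replay the documented rule by hand
        rel = np.abs([np.corrcoef(X[:, j], y)[0, 1] for j in range(8)])
        corr = np.corrcoef(X, rowvar=False)
        pairs = sorted(
            ((abs(corr[i, j]), i, j) for i in range(8) for j in range(i + 1, 8)
             if abs(corr[i, j]) > 0.90),
            reverse=True,
        )
        dropped = set()
        for _, i, j in pairs:
            if i in dropped or j in dropped:
                continue
            dropped.add(j if rel[i] >= rel[j] else i)
        expected = [f"D{j}" for j in range(8) if j not in dropped]
        assert out.names == expected

    def test_all_removed_is_error(self):
        with pytest.raises(ValueError):
            preprocess(_matrix(np.ones((10, 2))))

    def test_survivors_are_autoscaled(self):
        rng = np.random.default_rng(4)
        X = rng.normal(5, 3, size=(50, 3))
        out = preprocess(_matrix(X))
        assert np.allclose(out.X.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(out.X.std(axis=0), 1, atol=1e-12)


class TestFitMLR:
    def test_all_zero_descriptors_predict_intercept(self):
        from sertqsar.gamlr import MLRModel

        model = MLRModel(
            names=["a", "b", "c", "d", "e"],
            intercept=19.4436,
            coefficients=np.array([6.1825, -0.108, -11.4354, -0.1166, -10.2573]),
        )
        assert model.predict(np.zeros((1, 5)))[0] == pytest.approx(19.4436)

    def test_noiseless_recovery_to_machine_precision(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3))
        beta = np.array([1.5, -2.0, 0.7])
        y = 4.0 + X @ beta
        model = fit_mlr(X, y)
        assert model.intercept == pytest.approx(4.0, abs=1e-10)
        assert model.coefficients == pytest.approx(beta, abs=1e-10)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        model = fit_mlr(X, y)
        Xa = np.column_stack([np.ones(20), X])
        beta = np.linalg.solve(Xa.T @ Xa, Xa.T @ y)
        assert model.intercept == pytest.approx(beta[0])
        assert model.coefficients == pytest.approx(beta[1:])

    def test_rank_deficiency_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError):
            fit_mlr(X, np.arange(10.0))


class TestGASelect:
    def test_degenerate_search_returns_only_subset(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 4))
        y = X @ np.ones(4)
        model = ga_select(_matrix(X), y, GAConfig(k=4, generations=5, seed=0))
        assert sorted(model.names) == ["D0", "D1", "D2", "D3"]

    def test_planted_columns_recovered_across_seeds(self):
        """Planted 4-column signal among 50 noise columns is recovered in
        at least 9 of 10 seeds at the standard GA settings."""
        hits = 0
        for seed in range(10):
            matrix, y, truth = gen_descriptor_matrix(
                n=60, p=50, k_signal=4, noise_sd=0.1, seed=seed
            )
            pre = preprocess(matrix, activities=y)
            model = ga_select(pre, y, GAConfig(k=4, generations=500, seed=seed))
            hits += set(model.names) == set(truth["signal"])
        assert hits >= 9

    def test_beats_random_subsets(self):
        matrix, y, _ = gen_descriptor_matrix(n=50, p=30, k_signal=3, seed=11)
        pre = preprocess(matrix, activities=y)
        model = ga_select(pre, y, GAConfig(k=3, generations=100, seed=1))
        from sertqsar.gamlr import _q2_loo_hat

        rng = np.random.default_rng(2)
        for _ in range(100):
            subset = rng.choice(pre.X.shape[1], size=3, replace=False)
            assert model.fitness >= _q2_loo_hat(pre.X[:, subset], y) - 1e-12

    def test_seed_determinism(self):
        matrix, y, _ = gen_descriptor_matrix(n=40, p=20, k_signal=3, seed=3)
        pre = preprocess(matrix, activities=y)
        a = ga_select(pre, y, GAConfig(k=3, generations=30, seed=9))
        b = ga_select(pre, y, GAConfig(k=3, generations=30, seed=9))
        assert a.names == b.names

    def test_end_to_end_coefficient_recovery(self):
        """preprocess -> ga_select -> fit recovers generating coefficients
        within two standard errors (autoscaling rescales them)."""
        matrix, y, truth = gen_descriptor_matrix(
            n=80, p=30, k_signal=4, noise_sd=0.1, seed=13
        )
        raw_sd = matrix.X[:, :4].std(axis=0, ddof=0)
        pre = preprocess(matrix, activities=y)
        model = ga_select(pre, y, GAConfig(k=4, generations=300, seed=13))
        assert set(model.names) == set(truth["signal"])
        order = [model.names.index(n) for n in truth["signal"]]
        scaled_truth = truth["coefficients"] * raw_sd
        resid = y - model.predict(pre.X[:, [pre.names.index(n) for n in model.names]])
        se = np.sqrt((resid**2).sum() / (80 - 5)) / np.sqrt(80)
        assert np.allclose(model.coefficients[order], scaled_truth, atol=4 * se)
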