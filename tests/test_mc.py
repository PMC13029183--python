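"""Monte Carlo correlation-weight optimization."""

from collections import Counter

import numpy as np
import pytest

from sertqsar.attributes import AttributeInventory
from sertqsar.mc import (
    CalibratedModel,
    MCConfig,
    WeightTable,
    calibrate,
    compute_dcw,
    initialize_weights,
    mark_rare,
    optimize,
    select_hyperparams,
)


def _inv(mid, counts):
    return AttributeInventory(mid, Counter(counts))


def _random_problem(seed=0, n=10, n_codes=15):
    rng = np.random.default_rng(seed)
    codes = [f"code{j:02d}" for j in range(n_codes)]
    invs = [
        _inv(f"m{i}", {c: int(rng.integers(0, 4)) for c in codes})
        for i in range(n)
    ]
    return codes, invs


class TestMarkRare:
    def test_t1_nothing_is_rare(self):
        _, invs = _random_problem()
        assert mark_rare(invs, 1) == set()

    def test_definition_by_molecule_presence(self):
        invs = [_inv("a", {"X": 2}), _inv("b", {"X": 1}), _inv("c", {"Y": 1})]
        assert "X" not in mark_rare(invs, 2)
        assert "Y" in mark_rare(invs, 2)

    def test_matches_brute_force_count(self):
        codes, invs = _random_problem(seed=3)
        rare = mark_rare(invs, 3)
        for c in codes:
            present = sum(1 for i in invs if i.counts.get(c, 0) > 0)
            assert (c in rare) == (present < 3)

    def test_empty_training_set(self):
        with pytest.raises(ValueError):
            mark_rare([], 1)


class TestInitialize:
    def test_weights_within_band_and_rare_zero(self):
        table = initialize_weights({"a", "b", "r"}, seed=4, rare={"r"})
        assert 0.99 <= table.weights["a"] <= 1.01
        assert table.weights["r"] == 0.0

    def test_seed_determinism(self):
        t1 = initialize_weights({"a", "b"}, seed=7)
        t2 = initialize_weights({"a", "b"}, seed=7)
        assert t1.weights == t2.weights


class TestDCW:
    def test_empty_inventory(self):
        table = WeightTable({"a": 1.0}, set(), 1, 0, 0)
        assert compute_dcw(_inv("m", {}), table) == 0.0

    def test_multiplicity_arithmetic(self):
        table = WeightTable({"a": 0.5, "b": 0.25}, set(), 1, 0, 0)
        assert compute_dcw(_inv("m", {"a": 1, "b": 2}), table) == 1.0

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(11)
        codes, invs = _random_problem(seed=11)
        w = {c: float(rng.normal()) for c in codes}
        table = WeightTable(w, set(), 1, 0, 0)
        for inv in invs:
            expected = sum(w[c] * k for c, k in inv.counts.items())
            assert compute_dcw(inv, table) == pytest.approx(expected)

    def test_linearity_in_weight_tables(self):
        rng = np.random.default_rng(2)
        codes, invs = _random_problem(seed=2)
        wa = {c: float(rng.normal()) for c in codes}
        wb = {c: float(rng.normal()) for c in codes}
        wsum = {c: wa[c] + wb[c] for c in codes}
        for inv in invs:
            assert compute_dcw(inv, WeightTable(wsum, set(), 1, 0, 0)) == pytest.approx(
                compute_dcw(inv, WeightTable(wa, set(), 1, 0, 0))
                + compute_dcw(inv, WeightTable(wb, set(), 1, 0, 0))
            )

    def test_rare_attribute_never_influences_predictions(self):
        table = WeightTable({"a": 1.0, "r": 123.0}, {"r"}, 1, 0, 0)
        model = CalibratedModel(table, c0=0.0, c1=1.0)
        inv = _inv("m", {"a": 2, "r": 5})
        before = model.predict(inv)
        table.weights["r"] = -999.0
        assert model.predict(inv) == before


def _planted(seed=0, n=40, noise=0.05, n_codes=12):
    rng = np.random.default_rng(seed)
    codes = [f"c{j}" for j in range(n_codes)]
    effects = {c: float(rng.uniform(-1, 1)) for c in codes}
    invs, y = [], []
    for i in range(n):
        counts = {c: int(rng.integers(0, 3)) for c in codes}
        invs.append(_inv(f"m{i}", counts))
        y.append(
            sum(effects[c] * k for c, k in counts.items()) + rng.normal(0, noise)
        )
    return codes, effects, invs, np.array(y)


class TestOptimize:
    def test_zero_epochs_returns_initialization(self):
        _, _, invs, y = _planted()
        cfg = MCConfig(T=1, n_epoch=0, seed=5)
        table = optimize(invs, y, cfg)
        init = initialize_weights(set(table.weights), 5, rare=set())
        assert table.weights == init.weights

    def test_training_target_trace_monotone(self):
        _, _, invs, y = _planted(seed=1)
        trace = []
        optimize(invs, y, MCConfig(T=1, n_epoch=15, seed=2), trace=trace)
        targets = [t["target"] for t in trace]
        assert all(b >= a for a, b in zip(targets, targets[1:]))

    def test_planted_additive_recovery(self):
        """Training r2 >= 0.9 within 30 epochs on additive data, sigma=0.05."""
        _, _, invs, y = _planted(seed=3, n=40, noise=0.05)
        trace = []
        table = optimize(invs, y, MCConfig(T=1, n_epoch=30, seed=3), trace=trace)
        assert trace[-1]["target"] >= 0.9

    def test_planted_sign_recovery(self):
        """Learned weight signs match planted effect signs for >=90% of the
        attributes with effects clearly above the noise level."""
        codes, effects, invs, y = _planted(seed=4, n=60, noise=0.05)
        table = optimize(invs, y, MCConfig(T=1, n_epoch=40, seed=4))
        mean_w = np.mean(list(table.weights.values()))
        strong = [c for c in codes if abs(effects[c]) > 0.3]
        agree = sum(
            1
            for c in strong
            if np.sign(table.weights[c] - mean_w) == np.sign(effects[c])
        )
        assert agree / len(strong) >= 0.9

    def test_degenerate_activities_rejected(self):
        _, _, invs, _ = _planted()
        with pytest.raises(ValueError):
            optimize(invs, np.ones(len(invs)), MCConfig())


class TestCalibrate:
    def test_exact_line(self):
        invs = [_inv("a", {"x": 1}), _inv("b", {"x": 2}), _inv("c", {"x": 3})]
        table = WeightTable({"x": 1.0}, set(), 1, 0, 0)
        model = calibrate(invs, np.array([2.0, 4.0, 6.0]), table)
        assert model.c0 == pytest.approx(0.0, abs=1e-12)
        assert model.c1 == pytest.approx(2.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(8)
        codes, invs = _random_problem(seed=8)
        w = {c: float(rng.normal()) for c in codes}
        table = WeightTable(w, set(), 1, 0, 0)
        y = rng.normal(7, 0.5, len(invs))
        model = calibrate(invs, y, table)
        dcw = np.array([compute_dcw(i, table) for i in invs])
        X = np.column_stack([np.ones(len(y)), dcw])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert model.c0 == pytest.approx(beta[0])
        assert model.c1 == pytest.approx(beta[1])

    def test_published_model_form_is_representable(self):
        """A model of the form pIC50 = 3.73 + 0.039*DCW evaluates as stated."""
        table = WeightTable({"x": 1.0}, set(), 1, 10, 0)
        model = CalibratedModel(table, c0=3.73, c1=0.039)
        assert model.predict_dcw(100.0) == pytest.approx(7.63)


class TestSelectHyperparams:
    def test_single_cell_grid(self):
        _, _, invs, y = _planted(seed=6, n=30)
        T, ne, model, hist = select_hyperparams(
            invs[:20], y[:20], invs[20:], y[20:], t_values=(1,), epoch_max=0, seed=1
        )
        assert (T, ne) == (1, 0)

    def test_optimized_epochs_win_when_they_help(self):
        _, _, invs, y = _planted(seed=7, n=40, noise=0.05)
        T, ne, model, hist = select_hyperparams(
            invs[:30], y[:30], invs[30:], y[30:], t_values=(1,), epoch_max=5, seed=2
        )
        per_epoch = hist[1]
        assert ne == int(np.nanargmax(per_epoch))
        assert per_epoch[ne] >= per_epoch[0]
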