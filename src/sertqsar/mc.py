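"""Monte Carlo optimization of attribute correlation weights.

The single molecular descriptor is the descriptor correlation weight

    DCW(T, Nepoch) = sum over attribute occurrences of CW(attribute),

where attributes occurring in fewer than T training molecules are "rare"
and pinned at CW = 0.  Correlation weights start at 1 +/- 0.01*Rnd and are
refined by a greedy Monte Carlo walk: per epoch, every active attribute is
visited in a randomized order and a uniform perturbation of its weight is
accepted iff the training target (squared correlation between DCW and
activity) improves.  The final model is the ordinary least-squares line
pIC50 = C0 + C1 * DCW fitted on the training set; hyperparameters
(T, Nepoch) are chosen by external test-set r2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attributes import AttributeInventory

__all__ = [
    "MCConfig",
    "WeightTable",
    "CalibratedModel",
    "mark_rare",
    "initialize_weights",
    "compute_dcw",
    "optimize",
    "calibrate",
    "select_hyperparams",
]


@dataclass
class MCConfig:
    T: int = 1
    n_epoch: int = 10
    n_runs: int = 3
    seed: int = 0
    delta: float = 0.1  # perturbation scale
    target_function: str = "r2"  # only plain r2 is implemented


@dataclass
class WeightTable:
    weights: dict[str, float]
    rare: set[str]
    T: int
    n_epoch: int
    seed: int

    def cw(self, code: str) -> float:
        if code in self.rare:
            return 0.0
        return self.weights.get(code, 0.0)


@dataclass
class CalibratedModel:
    weight_table: WeightTable
    c0: float
    c1: float
    train_stats: dict = field(default_factory=dict)

    def predict_dcw(self, dcw: float) -> float:
        return self.c0 + self.c1 * dcw

    def predict(self, inventory: AttributeInventory) -> float:
        return self.predict_dcw(compute_dcw(inventory, self.weight_table))


def mark_rare(inventories: list[AttributeInventory], T: int) -> set[str]:
    """Attributes present in fewer than T training molecules."""
    if not inventories:
        raise ValueError("empty training set")
    if T < 1:
        raise ValueError("T must be >= 1")
    presence: dict[str, int] = {}
    for inv in inventories:
        for code in inv.counts:
            if inv.counts[code] > 0:
                presence[code] = presence.get(code, 0) + 1
    return {code for code, k in presence.items() if k < T}


def initialize_weights(
    attributes: set[str], seed: int, rare: set[str] | None = None, T: int = 1
) -> WeightTable:
    """CW = 1 +/- 0.01*Rnd for active attributes, 0 for rare ones."""
    if not attributes:
        raise ValueError("empty attribute set")
    rare = rare or set()
    rng = np.random.default_rng(seed)
    order = sorted(attributes)
    weights = {}
    for code in order:
        weights[code] = 0.0 if code in rare else 1.0 + 0.01 * (2 * rng.random() - 1)
    return WeightTable(weights=weights, rare=set(rare), T=T, n_epoch=0, seed=seed)


def compute_dcw(inventory: AttributeInventory, table: WeightTable) -> float:
    """Sum of CW over attribute occurrences; unknown codes contribute 0."""
    return float(
        sum(k * table.cw(code) for code, k in inventory.counts.items())
    )


def _design_matrix(
    inventories: list[AttributeInventory], codes: list[str]
) -> np.ndarray:
    idx = {c: j for j, c in enumerate(codes)}
    X = np.zeros((len(inventories), len(codes)))
    for i, inv in enumerate(inventories):
        for code, k in inv.counts.items():
            j = idx.get(code)
            if j is not None:
                X[i, j] = k
    return X


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    sx = x - x.mean()
    sy = y - y.mean()
    denom = np.sqrt((sx**2).sum() * (sy**2).sum())
    if denom == 0:
        return 0.0
    return float(((sx * sy).sum() / denom) ** 2)


def optimize(
    inventories: list[AttributeInventory],
    activities: np.ndarray,
    config: MCConfig,
    rare: set[str] | None = None,
    trace: list[dict] | None = None,
) -> WeightTable:
    """Greedy Monte Carlo refinement of correlation weights.

    ``trace``, if supplied, receives one snapshot dict per epoch with the
    epoch's weight vector copy and training-target value, which the
    hyperparameter search uses to read off intermediate-epoch models.
    """
    if len(inventories) < 5:
        raise ValueError("need at least 5 training molecules")
    y = np.asarray(activities, dtype=float)
    if np.allclose(y.var(), 0):
        raise ValueError("degenerate activity vector (zero variance)")
    if rare is None:
        rare = mark_rare(inventories, config.T)
    codes = sorted({c for inv in inventories for c in inv.counts})
    table = initialize_weights(set(codes), config.seed, rare=rare, T=config.T)
    table.n_epoch = config.n_epoch

    active = [c for c in codes if c not in rare]
    X = _design_matrix(inventories, codes)
    col = {c: X[:, j] for j, c in enumerate(codes)}
    w = np.array([table.weights[c] for c in codes])
    dcw = X @ w
    target = _r2(dcw, y)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    pos = {c: j for j, c in enumerate(codes)}

    for _ in range(config.n_epoch):
        order = rng.permutation(len(active))
        for k in order:
            code = active[k]
            dw = config.delta * (2 * rng.random() - 1)
            # greedy acceptance; the mirrored step is tried when the first
            # direction does not improve the target
            for step in (dw, -dw):
                cand = dcw + step * col[code]
                cand_target = _r2(cand, y)
                if cand_target > target:
                    target = cand_target
                    dcw = cand
                    w[pos[code]] += step
                    break
        if trace is not None:
            trace.append(
                {"weights": dict(zip(codes, w.tolist())), "target": target}
            )
    table.weights = dict(zip(codes, w.tolist()))
    return table


def calibrate(
    inventories: list[AttributeInventory],
    activities: np.ndarray,
    table: WeightTable,
) -> CalibratedModel:
    """OLS line pIC50 = C0 + C1 * DCW on the training set."""
    y = np.asarray(activities, dtype=float)
    dcw = np.array([compute_dcw(inv, table) for inv in inventories])
    if np.allclose(dcw.var(), 0):
        raise ValueError("zero DCW variance; cannot calibrate")
    c1, c0 = np.polyfit(dcw, y, 1)
    pred = c0 + c1 * dcw
    resid = y - pred
    stats = {
        "r2": _r2(dcw, y),
        "rmse": float(np.sqrt((resid**2).mean())),
        "n": len(y),
    }
    return CalibratedModel(weight_table=table, c0=float(c0), c1=float(c1), train_stats=stats)


def select_hyperparams(
    train_inv: list[AttributeInventory],
    train_act: np.ndarray,
    test_inv: list[AttributeInventory],
    test_act: np.ndarray,
    t_values=(1, 2, 3, 4, 5),
    epoch_max: int = 50,
    seed: int = 0,
) -> tuple[int, int, CalibratedModel, dict]:
    """Grid search over (T, Nepoch) maximizing external test-set r2.

    For each T one Monte Carlo trajectory of ``epoch_max`` epochs is run
    and every intermediate epoch is scored on the test set, so the whole
    Nepoch range is evaluated from a single optimization.  Ties break to
    the smallest Nepoch, then the smallest T.
    """
    y_tr = np.asarray(train_act, dtype=float)
    y_te = np.asarray(test_act, dtype=float)
    best = None  # (test_r2, -n_epoch, -T, model)
    history: dict = {}
    for T in t_values:
        rare = mark_rare(train_inv, T)
        trace: list[dict] = []
        cfg = MCConfig(T=T, n_epoch=epoch_max, seed=seed)
        table = optimize(train_inv, y_tr, cfg, rare=rare, trace=trace)
        # epoch 0 = pure initialization
        init = initialize_weights(set(table.weights), seed, rare=rare, T=T)
        snapshots = [init.weights] + [t["weights"] for t in trace]
        per_epoch = []
        for n_epoch, wsnap in enumerate(snapshots):
            snap = WeightTable(dict(wsnap), set(rare), T, n_epoch, seed)
            try:
                model = calibrate(train_inv, y_tr, snap)
            except ValueError:
                per_epoch.append(float("nan"))
                continue
            pred = np.array([model.predict(inv) for inv in test_inv])
            r2_te = _r2(pred, y_te)
            per_epoch.append(r2_te)
            key = (r2_te, -n_epoch, -T)
            if best is None or key > best[0]:
                best = (key, T, n_epoch, model)
        history[T] = per_epoch
    _, T_star, epoch_star, model = best
    return T_star, epoch_star, model, history
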