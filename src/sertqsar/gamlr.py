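"""Genetic-algorithm descriptor selection with multiple linear regression.

Descriptor matrices are externally computed inputs (opaque named numeric
columns).  Preprocessing removes near-constant columns (variance < 0.01),
resolves highly intercorrelated pairs (|r| > 0.90, keeping the column
better correlated with the activity) and autoscales the survivors.  The
GA evolves fixed-size descriptor subsets with tournament selection,
uniform crossover, per-gene mutation and elitism of one; fitness is the
leave-one-out Q2 of the OLS fit, computed in closed form from the hat
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorMatrix",
    "GAConfig",
    "MLRModel",
    "preprocess",
    "fit_mlr",
    "ga_select",
]


@dataclass
class DescriptorMatrix:
    ids: list[str]
    names: list[str]
    X: np.ndarray
    note: str = ""

    @classmethod
    def from_frame(cls, df: pd.DataFrame, id_col: str = "id", note: str = "") -> "DescriptorMatrix":
        names = [c for c in df.columns if c != id_col]
        return cls(
            ids=[str(v) for v in df[id_col]],
            names=names,
            X=df[names].to_numpy(dtype=float),
            note=note,
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.X, columns=self.names)
        out.insert(0, "id", self.ids)
        return out


@dataclass
class GAConfig:
    k: int = 4
    generations: int = 500
    population: int = 10
    mutation_rate: float = 0.20
    elitism: int = 1
    tournament: int = 2
    fitness: str = "q2_loo"  # or "r2"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.mutation_rate < 1:
            raise ValueError("mutation rate must be in (0, 1)")


@dataclass
class MLRModel:
    names: list[str]
    intercept: float
    coefficients: np.ndarray
    fitness: float = float("nan")
    train_stats: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coefficients


def preprocess(
    matrix: DescriptorMatrix,
    activities: np.ndarray | None = None,
    variance_min: float = 0.01,
    corr_max: float = 0.90,
    scale: bool = True,
) -> DescriptorMatrix:
    """Variance filter, greedy correlation filter, autoscaling."""
    X, names = matrix.X, list(matrix.names)
    keep = [j for j in range(X.shape[1]) if np.var(X[:, j]) >= variance_min]
    if not keep:
        raise ValueError("all descriptors removed by the variance filter")
    X, names = X[:, keep], [names[j] for j in keep]

    if activities is not None:
        y = np.asarray(activities, dtype=float)
        relevance = np.abs(
            [np.corrcoef(X[:, j], y)[0, 1] for j in range(X.shape[1])]
        )
    else:
        relevance = np.var(X, axis=0)

    corr = np.corrcoef(X, rowvar=False)
    p = X.shape[1]
    pairs = [
        (abs(corr[i, j]), i, j)
        for i in range(p)
        for j in range(i + 1, p)
        if abs(corr[i, j]) > corr_max
    ]
    pairs.sort(reverse=True)
    dropped: set[int] = set()
    for _, i, j in pairs:
        if i in dropped or j in dropped:
            continue
        # keep the column more relevant to the activity; ties keep the first
        dropped.add(j if relevance[i] >= relevance[j] else i)
    keep2 = [j for j in range(p) if j not in dropped]
    X, names = X[:, keep2], [names[j] for j in keep2]
    if scale:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    return DescriptorMatrix(ids=matrix.ids, names=names, X=X, note=matrix.note)


def fit_mlr(X: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> MLRModel:
    """Ordinary least squares on a descriptor subset."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    Xa = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(Xa) < k + 1:
        raise ValueError("rank-deficient descriptor subset")
    beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    pred = Xa @ beta
    resid = y - pred
    sstot = float(((y - y.mean()) ** 2).sum())
    model = MLRModel(
        names=list(names) if names is not None else [f"x{j}" for j in range(k)],
        intercept=float(beta[0]),
        coefficients=beta[1:],
    )
    model.train_stats = {
        "r2": 1.0 - float((resid**2).sum()) / sstot,
        "rmse": float(np.sqrt((resid**2).mean())),
        "n": n,
    }
    return model


def _q2_loo_hat(X: np.ndarray, y: np.ndarray) -> float:
    """Closed-form LOO Q2 for OLS via PRESS = sum((e_i/(1-h_i))^2)."""
    n, k = X.shape
    Xa = np.column_stack([np.ones(n), X])
    gram = Xa.T @ Xa
    if np.linalg.matrix_rank(gram) < k + 1:
        return -np.inf
    ginv = np.linalg.inv(gram)
    beta = ginv @ Xa.T @ y
    resid = y - Xa @ beta
    h = np.einsum("ij,jk,ik->i", Xa, ginv, Xa)
    if np.any(h >= 1 - 1e-12):
        return -np.inf
    press = float(((resid / (1 - h)) ** 2).sum())
    return 1.0 - press / float(((y - y.mean()) ** 2).sum())


def _fitness(X, y, subset, kind) -> float:
    Xs = X[:, subset]
    if kind == "q2_loo":
        return _q2_loo_hat(Xs, y)
    try:
        return fit_mlr(Xs, y).train_stats["r2"]
    except ValueError:
        return -np.inf


def ga_select(
    matrix: DescriptorMatrix, activities: np.ndarray, config: GAConfig
) -> MLRModel:
    """Evolve fixed-size descriptor subsets; return the best MLR model."""
    X = matrix.X
    y = np.asarray(activities, dtype=float)
    n, p = X.shape
    if n <= config.k + 2:
        raise ValueError("too few training rows for the requested model size")
    if p < config.k:
        raise ValueError("fewer descriptors than the requested model size")
    rng = np.random.default_rng(config.seed)

    def random_subset():
        return tuple(sorted(rng.choice(p, size=config.k, replace=False)))

    if p == config.k:  # only one possible subset: nothing to evolve
        model = fit_mlr(X, y, names=list(matrix.names))
        model.fitness = _fitness(X, y, list(range(p)), config.fitness)
        return model
    pop = [random_subset() for _ in range(config.population)]
    fits = [_fitness(X, y, list(s), config.fitness) for s in pop]

    for _ in range(config.generations):
        order = np.argsort(fits)[::-1]
        newpop = [pop[j] for j in order[: config.elitism]]
        while len(newpop) < config.population:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                cand = rng.choice(len(pop), size=config.tournament, replace=False)
                parents.append(pop[max(cand, key=lambda j: fits[j])])
            # uniform crossover over the union of parent genes
            pool = list(set(parents[0]) | set(parents[1]))
            child = set(rng.choice(pool, size=min(config.k, len(pool)), replace=False))
            while len(child) < config.k:
                child.add(int(rng.integers(p)))
            # per-gene mutation
            child = list(child)
            for idx in range(len(child)):
                if rng.random() < config.mutation_rate:
                    repl = int(rng.integers(p))
                    if repl not in child:
                        child[idx] = repl
            newpop.append(tuple(sorted(child)))
        pop = newpop
        fits = [_fitness(X, y, list(s), config.fitness) for s in pop]

    best = max(range(len(pop)), key=lambda j: fits[j])
    subset = list(pop[best])
    model = fit_mlr(X[:, subset], y, names=[matrix.names[j] for j in subset])
    model.fitness = float(fits[best])
    return model
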