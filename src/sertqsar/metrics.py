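"""Model validation battery: fit statistics, cross-validation, CCC, IIC,
MAE-based classification, rm2 metrics, Y-randomization and leverage AD.

All statistics operate on plain observed/predicted vectors or on a
user-supplied fit procedure (``fit(X, y) -> predict`` callable), so the
same battery serves both the single-descriptor Monte Carlo models and the
multi-descriptor MLR models.

Conventions adopted where the literature varies:

* IIC = r * min(MAE-, MAE+) / max(MAE-, MAE+), the negative/positive
  residual subsets taken from obs - pred; an empty residual class gives a
  min-ratio of 0.
* MAE classes follow the Roy criteria relative to the training activity
  range: GOOD if MAE <= 0.1*range and MAE + 3*sd <= 0.2*range; BAD if
  MAE > 0.15*range or MAE + 3*sd > 0.25*range; else MODERATE.
* cRp2 = R * sqrt(R^2 - mean(Rr^2)); the pass threshold is 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "basic_stats",
    "ccc",
    "iic",
    "q2_loo",
    "q2_lmo",
    "y_randomization",
    "RandomizationReport",
    "rm2_block",
    "mae_classify",
    "leverage_ad",
    "LeverageAD",
    "friedman_lof",
]


def _check(obs, pred, min_n=3):
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("length mismatch between observed and predicted")
    if obs.size < min_n:
        raise ValueError(f"need at least {min_n} points")
    if np.allclose(obs.var(), 0):
        raise ValueError("zero variance in observed values")
    return obs, pred


def ccc(obs, pred) -> float:
    """Lin's concordance correlation coefficient."""
    obs, pred = _check(obs, pred)
    mx, my = obs.mean(), pred.mean()
    vx, vy = obs.var(), pred.var()
    cov = ((obs - mx) * (pred - my)).mean()
    return float(2 * cov / (vx + vy + (mx - my) ** 2))


def iic(obs, pred) -> float:
    """Index of ideality of correlation."""
    obs, pred = _check(obs, pred)
    r = float(np.corrcoef(obs, pred)[0, 1])
    resid = obs - pred
    if np.allclose(resid, 0):
        return r  # perfect predictions: balance ratio is taken as 1
    neg, pos = resid[resid < 0], resid[resid > 0]
    if len(neg) == 0 or len(pos) == 0:
        return 0.0
    mae_n, mae_p = np.abs(neg).mean(), np.abs(pos).mean()
    lo, hi = min(mae_n, mae_p), max(mae_n, mae_p)
    return float(r * lo / hi)


def basic_stats(obs, pred) -> dict:
    """r2, rmse, mae, s, F, CCC and IIC for one obs/pred pairing."""
    obs, pred = _check(obs, pred)
    n = obs.size
    r = float(np.corrcoef(obs, pred)[0, 1])
    r2 = r * r
    resid = obs - pred
    rmse = float(np.sqrt((resid**2).mean()))
    mae = float(np.abs(resid).mean())
    # standard error of estimate and F for the univariate regression obs~pred
    s = float(np.sqrt((resid**2).sum() / max(n - 2, 1)))
    f_stat = float(r2 / (1 - r2) * (n - 2)) if r2 < 1 else float("inf")
    return {
        "n": n,
        "r2": r2,
        "rmse": rmse,
        "mae": mae,
        "s": s,
        "F": f_stat,
        "ccc": ccc(obs, pred),
        "iic": iic(obs, pred),
    }


def q2_loo(fit_procedure, X, y) -> float:
    """Leave-one-out q2 = 1 - PRESS/SStot with full refits."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 points for cross-validation")
    press = 0.0
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        try:
            predict = fit_procedure(X[mask], y[mask])
        except Exception as exc:  # noqa: BLE001 - re-raise naming the fold
            raise RuntimeError(f"fit failed in LOO fold {i}") from exc
        press += float((y[i] - np.asarray(predict(X[i : i + 1]))[0]) ** 2)
    return 1.0 - press / float(((y - y.mean()) ** 2).sum())


def q2_lmo(fit_procedure, X, y, leave_fraction=0.2, reps=25, seed=0) -> float:
    """Leave-many-out q2 over disjoint left-out groups.

    Groups of size round(n*leave_fraction) are consumed from shuffled
    partitions of the data (reshuffling whenever a partition is
    exhausted), so with leave_fraction = 1/n and reps = n the statistic
    reduces exactly to leave-one-out.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 points for cross-validation")
    k = max(1, int(round(n * leave_fraction)))
    rng = np.random.default_rng(seed)
    groups: list[np.ndarray] = []
    press, held = 0.0, 0
    for rep in range(reps):
        if not groups:
            perm = rng.permutation(n)
            groups = [perm[i : i + k] for i in range(0, n - k + 1, k)]
        out = groups.pop(0)
        mask = np.ones(n, bool)
        mask[out] = False
        try:
            predict = fit_procedure(X[mask], y[mask])
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"fit failed in LMO repetition {rep}") from exc
        pred = np.asarray(predict(X[out]))
        press += float(((y[out] - pred) ** 2).sum())
        held += len(out)
    sstot = float(((y - y.mean()) ** 2).sum()) * held / n
    return 1.0 - press / sstot


@dataclass
class RandomizationReport:
    n_permutations: int
    n_runs: int
    mean_rr2: float
    r2: float
    crp2: float
    passed: bool


def y_randomization(
    fit_procedure, X, y, n_permutations=1000, n_runs=10, seed=0
) -> RandomizationReport:
    """Response-permutation test with the cRp2 statistic.

    The unpermuted model's training R2 is compared against the mean R2 of
    models refit on permuted activities; cRp2 = R*sqrt(R2 - mean Rr2) must
    exceed 0.5 for the model to pass.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 5:
        raise ValueError("need at least 5 points")
    predict = fit_procedure(X, y)
    r2 = float(np.corrcoef(y, np.asarray(predict(X)))[0, 1] ** 2)
    rng = np.random.default_rng(seed)
    rr2 = []
    for _ in range(n_runs):
        for _ in range(n_permutations):
            yp = rng.permutation(y)
            pred = np.asarray(fit_procedure(X, yp)(X))
            if np.allclose(np.var(pred), 0):
                rr2.append(0.0)
            else:
                rr2.append(float(np.corrcoef(yp, pred)[0, 1] ** 2))
    mean_rr2 = float(np.mean(rr2))
    inner = r2 - mean_rr2
    crp2 = float(np.sqrt(r2) * np.sqrt(inner)) if inner > 0 else 0.0
    return RandomizationReport(
        n_permutations=n_permutations,
        n_runs=n_runs,
        mean_rr2=mean_rr2,
        r2=r2,
        crp2=crp2,
        passed=crp2 > 0.5,
    )


def _through_origin(x, y):
    """Slope k and r2_o of the regression through the origin of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    k = float((x * y).sum() / (x * x).sum())
    resid = y - k * x
    sstot = float(((y - y.mean()) ** 2).sum())
    return k, 1.0 - float((resid**2).sum()) / sstot


def rm2_block(obs, pred) -> dict:
    """rm2 external-validation metrics in both axis orientations.

    Unprimed: pred on x, obs on y.  Primed: obs on x, pred on y.
    rm2 = r2 * (1 - sqrt(r2 - r2o)); Clos = |r2o - r'2o|.
    """
    obs, pred = _check(obs, pred)
    if np.allclose(obs, 0) or np.allclose(pred, 0):
        raise ValueError("zero vectors")
    r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    k, r2o = _through_origin(pred, obs)
    kp, r2o_p = _through_origin(obs, pred)
    rm2 = r2 * (1 - np.sqrt(max(r2 - r2o, 0)))
    rm2_p = r2 * (1 - np.sqrt(max(r2 - r2o_p, 0)))
    clos = abs(r2o - r2o_p)
    return {
        "r2": r2,
        "rm2": float(rm2),
        "rm2_prime": float(rm2_p),
        "k": k,
        "k_prime": kp,
        "r2o": r2o,
        "r2o_prime": r2o_p,
        "clos": float(clos),
    }


def mae_classify(obs, pred, train_range: float) -> str:
    """Roy MAE-based model-quality class relative to the training range."""
    obs, pred = _check(obs, pred)
    if train_range <= 0:
        raise ValueError("training activity range must be positive")
    resid = np.abs(obs - pred)
    mae = float(resid.mean())
    sd = float(resid.std(ddof=0))
    if mae <= 0.1 * train_range and mae + 3 * sd <= 0.2 * train_range:
        return "GOOD"
    if mae > 0.15 * train_range or mae + 3 * sd > 0.25 * train_range:
        return "BAD"
    return "MODERATE"


@dataclass
class LeverageAD:
    h: np.ndarray
    h_star: float
    std_residuals: np.ndarray
    leverage_out: np.ndarray
    response_out: np.ndarray


def leverage_ad(X, residuals) -> LeverageAD:
    """Williams-plot quantities from the fitted design matrix.

    ``X`` is the n x p descriptor matrix used in the fit (intercept added
    here); h* = 3(p+1)/n, response outliers lie outside +/-3 internally
    studentized residuals.
    """
    X = np.asarray(X, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    n, p = X.shape
    Xa = np.column_stack([np.ones(n), X])
    gram = Xa.T @ Xa
    if np.linalg.matrix_rank(gram) < p + 1:
        raise ValueError("rank-deficient design matrix")
    hat = Xa @ np.linalg.solve(gram, Xa.T)
    h = np.diag(hat).copy()
    h_star = 3.0 * (p + 1) / n
    dof = max(n - p - 1, 1)
    s2 = float((residuals**2).sum() / dof)
    denom = np.sqrt(np.clip(s2 * (1 - h), 1e-30, None))
    std_res = residuals / denom
    return LeverageAD(
        h=h,
        h_star=h_star,
        std_residuals=std_res,
        leverage_out=h > h_star,
        response_out=np.abs(std_res) > 3,
    )


def friedman_lof(residuals, n_params: int, n: int, d: float = 0.5) -> float:
    """Friedman lack-of-fit: (RSS/n) / (1 - (c + d*p)/n)^2 with c = p + 1."""
    residuals = np.asarray(residuals, dtype=float)
    c = n_params + 1
    denom = 1.0 - (c + d * n_params) / n
    if denom <= 0:
        raise ValueError("too many parameters for the sample size")
    return float((residuals**2).sum() / n / denom**2)
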