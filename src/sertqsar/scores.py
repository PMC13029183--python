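"""Structure-score analytics: docking-score correlations and binding-pose
metadynamics (BPMD) summary scores.

``correlate_scores`` relates docking scores to predicted potencies
(Pearson with the t-distribution p-value, Spearman on midranks with an
exact permutation p below n=8).  The BPMD scores summarize pose-stability
trajectories: PoseScore is the mean ligand RMSD over replicas, PersScore
the fraction of final-window frames retaining at least the initial
hydrogen-bond count, and CompScore = PoseScore - 5 * PersScore (lower is
more stable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PoseTrajectorySummary",
    "correlate_scores",
    "pose_score",
    "pers_score",
    "comp_score",
    "load_score_table",
]


@dataclass
class PoseTrajectorySummary:
    """Per-replica ligand RMSD and hydrogen-bond count series.

    ``times`` is the shared sampling grid in ns; ``rmsd`` and ``hbonds``
    are (replicas x frames) arrays.
    """

    times: np.ndarray
    rmsd: np.ndarray
    hbonds: np.ndarray
    initial_hbonds: int

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.rmsd = np.atleast_2d(np.asarray(self.rmsd, dtype=float))
        self.hbonds = np.atleast_2d(np.asarray(self.hbonds, dtype=float))
        if self.rmsd.shape[0] < 1:
            raise ValueError("need at least one replica")
        if np.any(self.rmsd < 0):
            raise ValueError("RMSD values must be non-negative")


def _spearman_exact_p(rho: float, x, y) -> float:
    """Two-sided permutation p-value for Spearman rho at small n."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    obs = abs(rho)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def correlate_scores(
    table: pd.DataFrame,
    score_column: str,
    activity_column: str = "pIC50",
    method: str = "pearson",
) -> tuple[float, float]:
    """(coefficient, two-sided p) for one score column vs activity."""
    x = table[score_column].to_numpy(dtype=float)
    y = table[activity_column].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 rows")
    if np.allclose(np.var(x), 0) or np.allclose(np.var(y), 0):
        raise ValueError("constant column")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
        if len(x) < 8:
            p = _spearman_exact_p(float(rho), x, y)
        return float(rho), float(p)
    raise ValueError(f"unknown method {method!r}")


def pose_score(summary: PoseTrajectorySummary) -> float:
    """Mean of per-replica mean RMSDs (Angstrom)."""
    return float(summary.rmsd.mean(axis=1).mean())


def pers_score(summary: PoseTrajectorySummary, window_ns: float = 2.0) -> float:
    """Hydrogen-bond persistence over the final window, in [0, 1]."""
    if summary.initial_hbonds <= 0:
        return 0.0
    t_end = summary.times[-1]
    mask = summary.times >= t_end - window_ns
    frac = (summary.hbonds[:, mask] >= summary.initial_hbonds).mean(axis=1)
    return float(np.clip(frac, 0, 1).mean())


def comp_score(pose: float, pers: float) -> float:
    """CompScore = PoseScore - 5 * PersScore."""
    if not 0.0 <= pers <= 1.0:
        raise ValueError("PersScore must lie in [0, 1]")
    if pose < 0:
        raise ValueError("PoseScore must be non-negative")
    return float(pose - 5.0 * pers)


def load_score_table(path) -> pd.DataFrame:
    """Read a docking-score table (TSV with id + score columns + pIC50)."""
    return pd.read_csv(path, sep="\t")
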