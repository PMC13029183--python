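"""Synthetic inputs with the statistical structure the analysis assumes.

The scaffold generator emulates the modeled inhibitor series: ~50
compounds sharing one central benzene scaffold carrying a CF3 group and a
(piperidinyl)methoxymethyl arm, varied through six substituent
subclasses (tetrazole/triazole heterocycles; ortho-, meta- and
para-substituted biaryls; polyfluorinated aryls; N-alkyl piperidines).
Activities are fragment-additive: pIC50 = baseline + planted substituent
effect (with position multipliers that penalize meta substitution) +
Gaussian noise.  Ground truth is always returned so recovery tests can
check that models find the planted effects.

The other generators produce descriptor matrices with planted linear
signal for the GA-MLR branch, pose-stability trajectories for the BPMD
scores, and docking-score tables linearly anti-correlated with activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .attributes import local_attributes, tokenize_smiles
from .dataset import CompoundRecord
from .gamlr import DescriptorMatrix
from .scores import PoseTrajectorySummary

__all__ = [
    "ScaffoldSpec",
    "SyntheticTruth",
    "PLANTED_WEIGHTS",
    "gen_scaffold_dataset",
    "gen_descriptor_matrix",
    "gen_pose_trajectories",
    "gen_docking_scores",
    "CENTRAL_TAIL",
]

# Central scaffold written as the shared SMILES tail; every compound is
# head + tail, so substituent context stays in one SMILES dialect.
CENTRAL_TAIL = "c1cc(COCC2(CCNCC2)c2ccccc2)cc(c1)C(F)(F)F"

_POSITION_RING = {
    "ortho": "{}c1ccccc1",
    "meta": "{}c1cccc(c1)",
    "para": "{}c1ccc(cc1)",
}
# meta substitution is planted as the least favorable position
_POSITION_OFFSET = {"ortho": 0.0, "meta": -0.35, "para": 0.2}

_BIARYL_SUBS = (
    "F", "Cl", "Br", "C", "CC", "CCC", "CC(C)", "FC(F)(F)",
    "N#C", "CO", "OC", "CCO", "C=C", "CC(C)C", "CN", "CCN",
)

_HETEROCYCLE_HEADS = (
    "Cn1nnc(n1)",
    "Cn1ncc(n1)",
    "Cn1cnc(n1)",
    "Cn1ccc(n1)",
    "CCn1nnc(n1)",
    "Cc1nnc(o1)",
    "Cc1nnc(s1)",
)

_POLYFLUORO_HEADS = (
    "Fc1ccc(F)cc1",
    "Fc1cc(F)ccc1",
    "Fc1cc(F)cc(F)c1",
    "Fc1ccc(F)c(F)c1",
    "Fc1cccc(F)c1",
    "Fc1c(F)cccc1",
    "Fc1cc(F)c(F)cc1",
    "FC(F)(F)c1ccc(F)cc1",
    "FC(F)(F)c1cccc(F)c1",
)

_PIPERIDINE_HEADS = (
    "CN3CCC(CC3)",
    "CCN3CCC(CC3)",
    "CCCN3CCC(CC3)",
    "CC(C)N3CCC(CC3)",
    "CCCCN3CCC(CC3)",
)

# The planted truth lives directly in attribute space: each molecule's
# fragment effect is the count-weighted sum of these attribute-code
# weights over its own local-attribute inventory.  The generating model
# is therefore itself a correlation-weight model, globally consistent
# across subclasses (an F shared by a polyfluorinated head and a
# fluoro-biaryl head contributes identically), and the position windows
# "1...c...(..." / "c...c...c..." encode the meta-position penalty
# (meta -0.35, para +0.20 relative to ortho).
PLANTED_WEIGHTS = {
    "c...F.......": 0.28,   # aromatic F written Fc
    "c...(...F...": 0.22,   # aromatic F written (F)
    "n...........": 0.20,   # aromatic ring nitrogen
    "N...#.......": 0.35,   # nitrile
    "Cl..........": 0.35,
    "Br..........": 0.28,
    "N...C.......": -0.50,  # aliphatic amine
    "C...C.......": -0.08,  # alkyl chain growth
    "O...C.......": -0.18,  # ether/alkoxy
    "c...C.......": 0.10,   # alkyl on aromatic ring
    "1...c...(...": -0.22,  # ring-junction window; encodes the meta penalty
    "c...c...c...": -0.10,  # unsubstituted aromatic stretch
}

# subclass composition of the default 50-compound series
_SUBCLASS_COUNTS = {
    "heterocycle": 6,
    "ortho": 7,
    "meta": 7,
    "para": 16,
    "polyfluoro": 9,
    "piperidine": 5,
}


@dataclass
class ScaffoldSpec:
    n: int = 50
    baseline: float = 7.0
    noise_sd: float = 0.1
    seed: int = 0
    tail: str = CENTRAL_TAIL

    def __post_init__(self):
        if self.n < 10:
            raise ValueError("need n >= 10")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated scaffold dataset."""

    table: pd.DataFrame
    planted_weights: dict[str, float]
    baseline: float


def _subclass_counts(n: int) -> dict[str, int]:
    total = sum(_SUBCLASS_COUNTS.values())
    counts = {k: max(1, int(round(v * n / total))) for k, v in _SUBCLASS_COUNTS.items()}
    # adjust the largest subclass so counts sum exactly to n
    diff = n - sum(counts.values())
    counts["para"] += diff
    return counts


def _planted_effect(smiles: str, reference: dict | None = None) -> float:
    counts = local_attributes(tokenize_smiles(smiles))
    eff = sum(w * counts.get(code, 0) for code, w in PLANTED_WEIGHTS.items())
    if reference is not None:
        eff -= sum(w * reference.get(code, 0) for code, w in PLANTED_WEIGHTS.items())
    return float(eff)


def gen_scaffold_dataset(
    spec: ScaffoldSpec | None = None,
) -> tuple[list[CompoundRecord], SyntheticTruth]:
    """Scaffold series plus its ground-truth effect table."""
    spec = spec or ScaffoldSpec()
    rng = np.random.default_rng(spec.seed)
    counts = _subclass_counts(spec.n)

    pool: list[tuple[str, str, str]] = []  # (subclass, label, head)
    for head in _HETEROCYCLE_HEADS:
        pool.append(("heterocycle", head, head))
    for pos in ("ortho", "meta", "para"):
        for sub in _BIARYL_SUBS:
            pool.append((pos, f"{sub}@{pos}", _POSITION_RING[pos].format(sub)))
    for head in _POLYFLUORO_HEADS:
        pool.append(("polyfluoro", head, head))
    for head in _PIPERIDINE_HEADS:
        pool.append(("piperidine", head, head))

    # effects are measured relative to the plain phenyl (ortho-H) analog
    reference = local_attributes(tokenize_smiles("c1ccccc1" + spec.tail))

    records: list[CompoundRecord] = []
    truth_rows = []
    used: set[str] = set()
    idx = 0
    for subclass, k in counts.items():
        choices = [c for c in pool if c[0] == subclass]
        # sample without replacement while possible, then with replacement
        order = rng.permutation(len(choices))
        picks = [choices[j] for j in order]
        while len(picks) < k:
            picks.append(choices[int(rng.integers(len(choices)))])
        taken = 0
        for subclass_, label, head in picks:
            if taken >= k:
                break
            smiles = head + spec.tail
            if smiles in used and len(picks) > k:
                continue
            if Chem.MolFromSmiles(smiles) is None:  # pragma: no cover
                continue
            used.add(smiles)
            idx += 1
            taken += 1
            effect = _planted_effect(smiles, reference)
            clean = spec.baseline + effect
            pic50 = clean + rng.normal(0, spec.noise_sd)
            records.append(CompoundRecord(f"M{idx:03d}", smiles, float(pic50)))
            truth_rows.append(
                {
                    "id": f"M{idx:03d}",
                    "smiles": smiles,
                    "subclass": subclass_,
                    "fragment": label,
                    "effect": effect,
                    "pic50_clean": clean,
                    "pic50": float(pic50),
                }
            )
    truth = SyntheticTruth(
        table=pd.DataFrame(truth_rows),
        planted_weights=dict(PLANTED_WEIGHTS),
        baseline=spec.baseline,
    )
    return records, truth


def gen_descriptor_matrix(
    n: int = 60,
    p: int = 50,
    k_signal: int = 4,
    coefficients=None,
    noise_sd: float = 0.1,
    seed: int = 0,
    n_collinear: int = 0,
    n_constant: int = 0,
) -> tuple[DescriptorMatrix, np.ndarray, dict]:
    """Standard-normal descriptors with a planted linear signal."""
    if k_signal > p:
        raise ValueError("k_signal cannot exceed p")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if coefficients is None:
        coefficients = np.linspace(1.0, 2.0, k_signal)
    coefficients = np.asarray(coefficients, dtype=float)
    y = X[:, :k_signal] @ coefficients + rng.normal(0, noise_sd, size=n)
    names = [f"D{j:03d}" for j in range(p)]
    cols = [X]
    for j in range(n_collinear):
        cols.append(X[:, [j % p]])  # exact duplicates exercise the |r| filter
        names.append(f"D{j % p:03d}_dup")
    for j in range(n_constant):
        cols.append(np.full((n, 1), 3.14))
        names.append(f"CONST{j}")
    Xfull = np.hstack(cols)
    matrix = DescriptorMatrix(
        ids=[f"M{i:03d}" for i in range(1, n + 1)],
        names=names,
        X=Xfull,
        note="synthetic planted-signal matrix",
    )
    truth = {"signal": names[:k_signal], "coefficients": coefficients}
    return matrix, y, truth


def gen_pose_trajectories(
    stable: bool,
    replicas: int = 10,
    duration_ns: float = 10.0,
    dt_ns: float = 0.1,
    seed: int = 0,
    plateau: float = 1.0,
    noise_sd: float = 0.15,
    drift_per_ns: float = 0.35,
    initial_hbonds: int = 2,
) -> PoseTrajectorySummary:
    """RMSD/hydrogen-bond series for a stably or unstably bound pose."""
    if replicas < 1:
        raise ValueError("need at least one replica")
    rng = np.random.default_rng(seed)
    times = np.arange(dt_ns, duration_ns + dt_ns / 2, dt_ns)
    base = np.full((replicas, times.size), plateau)
    if not stable:
        base = base + drift_per_ns * times[None, :]
    rmsd = np.clip(base + rng.normal(0, noise_sd, base.shape), 0, None)
    if stable:
        # hydrogen bonds held at or above the initial count in most frames
        hb = initial_hbonds + (rng.random(base.shape) < 0.1).astype(float)
        lost = rng.random(base.shape) < 0.05
        hb[lost] = initial_hbonds - 1
    else:
        decay = np.clip(1.0 - times / (0.4 * duration_ns), 0, 1)
        hb = (rng.random(base.shape) < decay[None, :]) * initial_hbonds
    if noise_sd == 0:
        rmsd = np.clip(base, 0, None)
    return PoseTrajectorySummary(
        times=times, rmsd=rmsd, hbonds=hb, initial_hbonds=initial_hbonds
    )


def gen_docking_scores(
    activities,
    slope: float = -20.0,
    intercept: float = 0.0,
    noise_sd: float = 10.0,
    seed: int = 0,
    ids=None,
) -> pd.DataFrame:
    """Docking-score table linearly related to activity (negative slope
    mimics better scores for more potent compounds)."""
    y = np.asarray(activities, dtype=float)
    rng = np.random.default_rng(seed)
    score = intercept + slope * y + rng.normal(0, noise_sd, size=y.size)
    if ids is None:
        ids = [f"M{i:03d}" for i in range(1, y.size + 1)]
    return pd.DataFrame({"id": ids, "MolDock": score, "pIC50": y})
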