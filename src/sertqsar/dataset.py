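"""Compound table I/O, activity-unit conversion, splits and diversity stats.

The canonical record is (id, SMILES, pIC50, subset).  Activities are held
internally as pIC50 = -log10(IC50 [M]); IC50 inputs in nM/uM/M are converted
on read when a unit is declared (never guessed).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs

__all__ = [
    "CompoundRecord",
    "SplitSpec",
    "read_dataset",
    "write_dataset",
    "make_split",
    "ic50_nM_to_pic50",
    "pic50_to_ic50_nM",
    "diversity_stats",
    "DatasetFormatError",
]

_UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "µM": 1e3, "M": 1e9, "mM": 1e6}


class DatasetFormatError(ValueError):
    pass


@dataclass
class CompoundRecord:
    id: str
    smiles: str
    pic50: float
    subset: str = "unassigned"  # train | test | unassigned


@dataclass
class SplitSpec:
    split_index: int = 1
    train_fraction: float = 0.75
    seed: int = 0
    max_reshuffles: int = 100

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def ic50_nM_to_pic50(ic50_nm: float) -> float:
    """pIC50 from an IC50 given in nanomolar."""
    if not ic50_nm > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nm}")
    return 9.0 - math.log10(ic50_nm)


def pic50_to_ic50_nM(pic50: float) -> float:
    """Exact inverse of :func:`ic50_nM_to_pic50`."""
    if not math.isfinite(pic50):
        raise ValueError("pIC50 must be finite")
    return 10.0 ** (9.0 - pic50)


def read_dataset(
    path,
    fmt: str | None = None,
    activity_unit: str = "pIC50",
) -> list[CompoundRecord]:
    """Read a compound table with columns id, smiles, activity[, subset].

    ``activity_unit`` is ``"pIC50"`` (default) or an IC50 unit in
    ``{"nM","uM","M","mM"}``; IC50 values are converted to pIC50.
    Rows sharing a canonical SMILES are collapsed to the first occurrence
    with a warning.
    """
    # explicit separator: delimiter sniffing mis-handles '#' in SMILES
    if fmt is None:
        fmt = "csv" if str(path).lower().endswith(".csv") else "tsv"
    df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",")
    cols = {c.lower(): c for c in df.columns}
    for need in ("id", "smiles"):
        if need not in cols:
            raise DatasetFormatError(f"missing required column {need!r}")
    act_col = next(
        (cols[c] for c in cols if c in ("activity", "pic50", "ic50", "ic50_nm")),
        None,
    )
    if act_col is None:
        raise DatasetFormatError("missing activity column (activity/pic50/ic50)")

    bad_smiles, bad_activity = [], []
    records: list[CompoundRecord] = []
    seen: dict[str, str] = {}
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        rid = str(getattr(row, cols["id"]))
        smi = str(getattr(row, cols["smiles"]))
        try:
            val = float(getattr(row, act_col))
            if not math.isfinite(val):
                raise ValueError
        except (TypeError, ValueError):
            bad_activity.append(rownum)
            continue
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            bad_smiles.append(rownum)
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            warnings.warn(
                f"duplicate structure in row {rownum} (same as id {seen[canon]}); dropped"
            )
            continue
        seen[canon] = rid
        if activity_unit != "pIC50":
            if activity_unit not in _UNIT_TO_NM:
                raise ValueError(f"unknown activity unit {activity_unit!r}")
            val = ic50_nM_to_pic50(val * _UNIT_TO_NM[activity_unit])
        subset = "unassigned"
        if "subset" in cols:
            subset = str(getattr(row, cols["subset"]))
        records.append(CompoundRecord(rid, smi, val, subset))
    if bad_smiles:
        raise DatasetFormatError(f"unparseable SMILES in rows {bad_smiles}")
    if bad_activity:
        raise DatasetFormatError(f"non-numeric activity in rows {bad_activity}")
    return records


def write_dataset(records: list[CompoundRecord], path, fmt: str = "tsv") -> None:
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "pic50": [r.pic50 for r in records],
            "subset": [r.subset for r in records],
        }
    )
    df.to_csv(path, sep="\t" if fmt == "tsv" else ",", index=False)


def make_split(records: list[CompoundRecord], spec: SplitSpec) -> list[CompoundRecord]:
    """Random train/test partition with activity-range coverage control.

    round(n * train_fraction) records become the training set.  Partitions
    whose test activities fall outside the training activity range are
    reshuffled (bounded retries) so both subsets cover comparable ranges.
    """
    n = len(records)
    if n < 8:
        raise ValueError(f"need at least 8 records to split, got {n}")
    n_train = int(round(n * spec.train_fraction))
    rng = np.random.default_rng((spec.seed, spec.split_index))
    acts = np.array([r.pic50 for r in records])
    for attempt in range(spec.max_reshuffles + 1):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        if acts[te].min() >= acts[tr].min() and acts[te].max() <= acts[tr].max():
            break
    else:  # pragma: no cover - loop always breaks or exhausts
        pass
    if attempt == spec.max_reshuffles:
        warnings.warn("could not achieve test-range containment; using last shuffle")
    out = []
    tr_set = set(tr.tolist())
    for i, r in enumerate(records):
        out.append(
            CompoundRecord(r.id, r.smiles, r.pic50, "train" if i in tr_set else "test")
        )
    return out


def _fingerprint(smiles: str):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DatasetFormatError(f"unparseable SMILES {smiles!r}")
    # hashed topological path fingerprint; parameters fixed for reproducibility
    return Chem.RDKFingerprint(mol, maxPath=7, fpSize=2048)


def diversity_stats(records: list[CompoundRecord], cutoffs=(0.70, 0.50)) -> dict:
    """Pairwise Tanimoto similarity summary over all n(n-1)/2 pairs."""
    if len(records) < 2:
        raise ValueError("need at least 2 records for diversity statistics")
    fps = [_fingerprint(r.smiles) for r in records]
    sims = []
    for i in range(len(fps)):
        sims.extend(DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1 :]))
    sims = np.asarray(sims)
    out = {
        "n_compounds": len(records),
        "n_pairs": len(sims),
        "mean": float(sims.mean()),
        "sd": float(sims.std(ddof=1)) if sims.size > 1 else 0.0,
        "min": float(sims.min()),
        "max": float(sims.max()),
    }
    for c in cutoffs:
        out[f"fraction_below_{c:.2f}"] = float((sims < c).mean())
    return out


def save_diversity(stats: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(stats, fh, indent=2)
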