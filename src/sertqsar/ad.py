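"""Applicability domain for Monte Carlo models via attribute statistical defects.

The defect of an attribute A measures how differently A is represented in
the training and external test sets:

    d(A) = |P_train(A) - P_test(A)| / (N_train(A) + N_test(A))

with P the fraction of a set's molecules containing A and N the count of
such molecules.  (The source equation prints a difference in the
denominator, which is degenerate whenever the counts match; the sum form
is the convention of the underlying methodology and is used here.)
A molecule's defect D is the multiplicity-weighted sum of d(A) over its
attributes, and it is an outlier iff D > 2 * Dav of its own set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attributes import AttributeInventory

__all__ = ["DefectReport", "attribute_defects", "molecule_defect", "flag_outliers", "defect_report"]


@dataclass
class DefectReport:
    attribute_defect: dict[str, float]
    molecule_defect: dict[str, float]
    dav_train: float
    dav_test: float
    outlier: dict[str, bool]


def _presence(inventories: list[AttributeInventory]) -> dict[str, int]:
    pres: dict[str, int] = {}
    for inv in inventories:
        for code, k in inv.counts.items():
            if k > 0:
                pres[code] = pres.get(code, 0) + 1
    return pres


def attribute_defects(
    train: list[AttributeInventory], test: list[AttributeInventory]
) -> dict[str, float]:
    """d(A) for every attribute seen in either set."""
    if not train or not test:
        raise ValueError("both sets must be non-empty")
    p_tr, p_te = _presence(train), _presence(test)
    out: dict[str, float] = {}
    for code in set(p_tr) | set(p_te):
        n_tr, n_te = p_tr.get(code, 0), p_te.get(code, 0)
        out[code] = abs(n_tr / len(train) - n_te / len(test)) / (n_tr + n_te)
    return out


def molecule_defect(inventory: AttributeInventory, defects: dict[str, float]) -> float:
    """D = multiplicity-weighted sum of d(A); attributes absent from the
    defect map (never seen during modeling) contribute 0."""
    return float(
        sum(k * defects.get(code, 0.0) for code, k in inventory.counts.items())
    )


def flag_outliers(ds: list[float]) -> tuple[float, list[bool]]:
    """Per-set outlier rule D > 2 * Dav; returns (Dav, flags)."""
    if not ds:
        raise ValueError("empty set")
    dav = float(np.mean(ds))
    return dav, [d > 2 * dav for d in ds]


def defect_report(
    train: list[AttributeInventory], test: list[AttributeInventory]
) -> DefectReport:
    defects = attribute_defects(train, test)
    d_tr = [molecule_defect(inv, defects) for inv in train]
    d_te = [molecule_defect(inv, defects) for inv in test]
    dav_tr, fl_tr = flag_outliers(d_tr)
    dav_te, fl_te = flag_outliers(d_te)
    mol_d, outlier = {}, {}
    for inv, d, f in zip(train, d_tr, fl_tr):
        mol_d[inv.molecule_id] = d
        outlier[inv.molecule_id] = f
    for inv, d, f in zip(test, d_te, fl_te):
        mol_d[inv.molecule_id] = d
        outlier[inv.molecule_id] = f
    return DefectReport(defects, mol_d, dav_tr, dav_te, outlier)
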