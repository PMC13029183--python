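"""Fragment interpretation of a trained model and candidate enumeration.

Positive correlation weights mark activity-promoting attributes, negative
ones detractors.  New candidates are assembled by splicing substituent
SMILES fragments into template strings at marked sites: each substitution
site is a template string containing one ``{}`` placeholder, so the
assembled candidate stays in the same SMILES dialect the model was
trained on (the model consumes SMILES as written, not canonicalized).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from rdkit import Chem

from .attributes import AttributeInventory, extract_inventory
from .dataset import pic50_to_ic50_nM
from .mc import CalibratedModel, compute_dcw

__all__ = [
    "FragmentContribution",
    "SubstitutionSite",
    "CandidateMolecule",
    "rank_contributions",
    "enumerate_candidates",
    "score_candidates",
]


@dataclass
class FragmentContribution:
    code: str
    cw: float
    direction: str  # promoter | detractor
    support: int  # training molecules containing the attribute


@dataclass
class SubstitutionSite:
    label: str  # e.g. "ortho", "meta", "para"
    template: str  # SMILES with one "{}" placeholder


@dataclass
class CandidateMolecule:
    smiles: str
    parent: str
    edit: str
    dcw: float = float("nan")
    pic50_pred: float = float("nan")
    ic50_nm: float = float("nan")
    defect: float = float("nan")
    ad_outlier: bool = False
    novel_attributes: int = 0
    low_confidence: bool = False


def rank_contributions(
    model: CalibratedModel,
    train_inventories: list[AttributeInventory] | None = None,
) -> list[FragmentContribution]:
    """Non-rare attributes sorted by correlation weight, descending."""
    table = model.weight_table
    support: dict[str, int] = {}
    if train_inventories:
        for inv in train_inventories:
            for code in inv.counts:
                support[code] = support.get(code, 0) + 1
    out = []
    for code, cw in table.weights.items():
        if code in table.rare or cw == 0.0:
            continue
        out.append(
            FragmentContribution(
                code=code,
                cw=cw,
                direction="promoter" if cw > 0 else "detractor",
                support=support.get(code, 0),
            )
        )
    out.sort(key=lambda c: c.cw, reverse=True)
    return out


def enumerate_candidates(
    sites: list[SubstitutionSite],
    substituents: list[str],
    parent: str = "",
) -> list[CandidateMolecule]:
    """One candidate per (substituent, site); invalid assemblies dropped."""
    out = []
    for sub in substituents:
        for site in sites:
            smi = site.template.format(sub)
            if Chem.MolFromSmiles(smi) is None:
                warnings.warn(f"dropping unparseable candidate {smi!r}")
                continue
            out.append(
                CandidateMolecule(smiles=smi, parent=parent, edit=f"{sub}@{site.label}")
            )
    return out


def score_candidates(
    candidates: list[CandidateMolecule],
    model: CalibratedModel,
    attribute_defects: dict[str, float] | None = None,
    dav: float | None = None,
    max_novel: int = 5,
) -> list[CandidateMolecule]:
    """Predict activity for each candidate and rank by predicted pIC50."""
    known = set(model.weight_table.weights)
    for cand in candidates:
        inv = extract_inventory(cand.smiles, cand.smiles)
        cand.dcw = compute_dcw(inv, model.weight_table)
        cand.pic50_pred = model.predict_dcw(cand.dcw)
        cand.ic50_nm = pic50_to_ic50_nM(cand.pic50_pred)
        cand.novel_attributes = sum(
            1 for code in inv.counts if code not in known
        )
        cand.low_confidence = cand.novel_attributes > max_novel
        if attribute_defects is not None:
            cand.defect = float(
                sum(
                    k * attribute_defects.get(code, 0.0)
                    for code, k in inv.counts.items()
                )
            )
            if dav is not None:
                cand.ad_outlier = cand.defect > 2 * dav
    # ties broken by SMILES so the ranking is input-order independent
    return sorted(candidates, key=lambda c: (-c.pic50_pred, c.smiles))
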