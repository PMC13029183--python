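import numpy as np
import pytest

from sertqsar.attributes import extract_inventory
from sertqsar.dataset import SplitSpec, make_split
from sertqsar.pipeline import packaged_table
from sertqsar.simulate import ScaffoldSpec, gen_scaffold_dataset

# the published worked-example molecule (tetrazole analog of the series)
WORKED_EXAMPLE_SMILES = "Cn1nnc(n1)c1cc(COCC2(CCNCC2)c2ccccc2)cc(c1)C(F)(F)F"


@pytest.fixture(scope="session")
def worked_example_table():
    return packaged_table("dcw_worked_example.tsv")


@pytest.fixture(scope="session")
def docking_table():
    return packaged_table("docking_scores.tsv")


@pytest.fixture(scope="session")
def designed_table():
    return packaged_table("designed_compounds.tsv")


@pytest.fixture(scope="session")
def scaffold_dataset():
    """Default synthetic scaffold series (n=50, sigma=0.1) with ground truth."""
    return gen_scaffold_dataset(ScaffoldSpec(seed=1))


@pytest.fixture(scope="session")
def scaffold_split(scaffold_dataset):
    """One 38/12 train/test split of the default series, with inventories."""
    records, truth = scaffold_dataset
    split = make_split(records, SplitSpec(split_index=1, seed=1))
    train = [r for r in split if r.subset == "train"]
    test = [r for r in split if r.subset == "test"]
    inv = {r.id: extract_inventory(r.smiles, r.id) for r in split}
    return {
        "train": train,
        "test": test,
        "inv_train": [inv[r.id] for r in train],
        "inv_test": [inv[r.id] for r in test],
        "y_train": np.array([r.pic50 for r in train]),
        "y_test": np.array([r.pic50 for r in test]),
        "truth": truth,
    }
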