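import numpy as np
import pytest

from cladeage.clade_data import CladeDataset, CladeRecord, TimeTree
from cladeage.synthetic_data import GeneratorSpec, generate_clade_dataset


def balanced_newick(labels, height: float) -> str:
    """Newick for a perfectly balanced ultrametric tree over ``labels``."""
    def sub(lbls, h, stem):
        if len(lbls) == 1:
            return f"{lbls[0]}:{stem}"
        half = len(lbls) // 2
        return (f"({sub(lbls[:half], h / 2, h / 2)},"
                f"{sub(lbls[half:], h / 2, h / 2)}):{stem}")
    half = len(labels) // 2
    return (f"({sub(labels[:half], height / 2, height / 2)},"
            f"{sub(labels[half:], height / 2, height / 2)});")


@pytest.fixture
def three_tip_tree() -> TimeTree:
    return TimeTree.from_newick("((A:10,B:10):5,C:15);")


@pytest.fixture
def balanced16_tree() -> TimeTree:
    labels = [f"T{i}" for i in range(16)]
    return TimeTree.from_newick(balanced_newick(labels, 40.0))


@pytest.fixture
def star_dataset() -> CladeDataset:
    """Star tree (polytomy resolved with zero-length branches): V = h*I."""
    n = 12
    rng = np.random.default_rng(1)
    newick = "(" + ",".join(f"S{i}:50" for i in range(n)) + ");"
    tree = TimeTree.from_newick(newick, allow_polytomies=True)
    richness = rng.integers(1, 500, size=n)
    records = [CladeRecord(f"S{i}", int(richness[i])) for i in range(n)]
    return CladeDataset(tree=tree, records=records)


@pytest.fixture
def constant_rate_dataset() -> CladeDataset:
    spec = GeneratorSpec(n_tips=120, richness_model="constant_rate",
                         lam=0.1, mu=0.05, seed=7)
    dataset, _ = generate_clade_dataset(spec)
    return dataset
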