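import io as _io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from pond_assembly import synthetic


@pytest.fixture(scope="session")
def genotypes10():
    """Ten well-separated 250 bp genotypes used across denoiser tests."""
    return synthetic.simulate_genotypes(10, 250, 5, seed=1)


@pytest.fixture(scope="session")
def toy_table():
    """3 OTUs x 4 samples with two groups, hand-enumerable."""
    return pd.DataFrame(
        {
            "a1": [10, 0, 2],
            "a2": [8, 1, 3],
            "b1": [0, 9, 2],
            "b2": [1, 11, 1],
        },
        index=["otuA", "otuB", "otuC"],
    )


@pytest.fixture(scope="session")
def toy_groups():
    return {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}


@pytest.fixture(scope="session")
def balanced_tree():
    """4-taxon balanced tree with unit branch lengths."""
    return TreeNode.read(_io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))


@pytest.fixture(scope="session")
def neutral_metacommunity():
    cfg = synthetic.MetacommunityConfig(niche_weight=0.0)
    return synthetic.simulate_metacommunity(cfg, seed=5)


def sparse_random_communities(tree, n_samples=12, richness=15, depth=300, seed=0):
    """Random equal-probability communities occupying subsets of the tips."""
    rng = np.random.default_rng(seed)
    otus = [t.name for t in tree.tips()]
    S = len(otus)
    cols = {}
    for i in range(n_samples):
        pick = rng.choice(S, richness, replace=False)
        v = np.zeros(S, dtype=int)
        v[pick] = rng.multinomial(depth, np.ones(richness) / richness)
        cols[f"s{i}"] = v
    return pd.DataFrame(cols, index=otus)
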