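import numpy as np
import pandas as pd
import pytest

import phyloprior as pp

T1 = "((A:1,B:1):1,C:2):0;"


@pytest.fixture
def t1():
    return pp.parse_newick(T1)


@pytest.fixture
def t1_probs():
    return pd.Series({"A": 0.5, "B": 0.5, "C": 0.1})


@pytest.fixture
def t1_matrix():
    # A and B confined to c1; C in c2 only
    frame = pd.DataFrame(
        {"A": [1, 0], "B": [1, 0], "C": [0, 1]},
        index=pd.Index(["c1", "c2"], name="cell"),
    )
    return pp.AssemblageMatrix(frame)


def random_tree_and_probs(rng, max_tips=12, min_tips=2, zero_one_probs=False):
    """A random Yule tree plus random extinction probabilities for each tip."""
    n = int(rng.integers(min_tips, max_tips + 1))
    tree = pp.simulate_tree(n, birth_rate=1.0, seed=int(rng.integers(2**31 - 1)))
    if zero_one_probs:
        vals = rng.choice([0.0, 0.3, 0.7, 1.0], size=n)
    else:
        vals = rng.uniform(0.01, 0.99, size=n)
    probs = pd.Series(vals, index=list(tree.tips))
    return tree, probs
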