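import numpy as np
import pytest

from lindiv import (
    CTMCModel,
    RegionSet,
    StatePosterior,
    parse_tree,
    simulate_yule,
)

TOY_NEWICK = "((A:1,B:1):2,(C:2,D:2):1);"


@pytest.fixture
def toy_tree():
    """4-tip caterpillar: cherries (A,B) at age 1 and (C,D) at age 2, root at 3."""
    tree, _ = parse_tree(text=TOY_NEWICK)
    return tree


@pytest.fixture
def regions2():
    return RegionSet(("I", "IV"))


def toy_nodes(tree):
    """(root, AB-node, CD-node) ids resolved by clade, not by numbering."""
    by_clade = {tree.descendant_tip_labels(v): v for v in tree.internal_nodes}
    return (
        by_clade[frozenset("ABCD")],
        by_clade[frozenset("AB")],
        by_clade[frozenset("CD")],
    )


@pytest.fixture
def toy_onehot(toy_tree, regions2):
    root, ab, cd = toy_nodes(toy_tree)
    return StatePosterior(regions2, {root: [1, 0], cd: [1, 0], ab: [0, 1]})


@pytest.fixture
def toy_probs(toy_tree, regions2):
    root, ab, cd = toy_nodes(toy_tree)
    return StatePosterior(
        regions2, {root: [0.7, 0.3], cd: [0.6, 0.4], ab: [0.1, 0.9]}
    )


def random_tree(rng, n_min=2, n_max=6):
    return simulate_yule(int(rng.integers(n_min, n_max + 1)), 1.0, rng)


def random_ctmc(rng, k=4):
    """Random irreducible all-rates-differ chain with stationary root prior."""
    Q = rng.gamma(1.0, 0.5, size=(k, k))
    return CTMCModel.from_rates(Q, "ard")


def random_tip_states(rng, tree, regions):
    return {
        tree.label(v): regions.labels[int(rng.integers(regions.k))]
        for v in tree.tips
    }
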