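"""Shared fixtures: small hand-built trees and random-state generators."""

import numpy as np
import pytest

from mscoal import simulate as sim
from mscoal.trees import GeneTree, SpeciesTree


@pytest.fixture
def rng():
    return np.random.default_rng(20170414)


@pytest.fixture
def two_species_state():
    """The two-species worked example: speciation at T1=1.0, one gene tree
    with tips a, b coalescing at t1=1.5, species rates 0.7/1.0/1.3."""
    st = SpeciesTree.from_newick("(A:1.0,B:1.0);")
    gt = GeneTree.from_newick("(a:1.5,b:1.5);")
    mapping = {"a": "A", "b": "B"}
    st.rate = {st.node_by_label("A").id: 0.7,
               st.node_by_label("B").id: 1.0,
               st.root.id: 1.3}
    return st, gt, mapping


def random_compatible_pair(rng, n_species=4, samples=2, birth=100.0,
                           death=30.0, pop_shape=2.0, pop_scale=0.002):
    """A random species tree plus an MSC gene tree guaranteed compatible."""
    st = sim.simulate_birth_death_tree(n_species, birth, death, rng)
    sim.simulate_pop_sizes(st, "gamma", pop_shape, pop_scale, rng)
    gt, mapping = sim.simulate_msc_gene_tree(st, samples, rng)
    return st, gt, mapping


def chi2_two_sample(counts_a: dict, counts_b: dict, min_cell: int = 10) -> float:
    """Two-sample chi-square p-value over a shared category set, pooling
    rare categories."""
    from scipy import stats as ss

    keys = sorted(set(counts_a) | set(counts_b), key=str)
    a = np.array([counts_a.get(k, 0) for k in keys], dtype=float)
    b = np.array([counts_b.get(k, 0) for k in keys], dtype=float)
    keep = (a + b) >= min_cell
    a = np.append(a[keep], a[~keep].sum())
    b = np.append(b[keep], b[~keep].sum())
    tbl = np.vstack([a, b])
    tbl = tbl[:, tbl.sum(axis=0) > 0]
    return float(ss.chi2_contingency(tbl).pvalue)


def assert_tree_sound(tree):
    """Structural soundness: reachability, parent links, height ordering."""
    reach = set()
    stack = [tree.root]
    while stack:
        n = stack.pop()
        reach.add(n.id)
        for c in n.children:
            assert c.parent is n
            stack.append(c)
    assert reach == set(tree.nodes)
    tree.validate()
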