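"""Shared fixtures and independent oracles.

The brute-force likelihood here enumerates every internal-state assignment
directly from the model definition; it shares no code with the pruning
engine it is used to check.
"""

import itertools

import numpy as np
import pytest

from rsaevol.io import AMINO_ACIDS, LabeledTree, ResidueAlignment
from rsaevol.revmodel import RevModel


@pytest.fixture
def quartet_tree():
    return LabeledTree.from_newick("((a,b),(c,d));")


@pytest.fixture
def six_taxon_tree():
    """Trifurcating root: every branch length is identifiable."""
    return LabeledTree.from_newick("((a,b)X,(c,d)Y,(e,f)Z);")


@pytest.fixture
def rooted_six_taxon_tree():
    """Rooted binary balanced shape with four inner branches."""
    return LabeledTree.from_newick("(((a,b)N1,(c,d)N2)N3,(e,f)N4);")


@pytest.fixture
def dna_model():
    return RevModel.random("ACGT", seed=11)


@pytest.fixture
def jc4():
    return RevModel.equal_rates("ACGT")


@pytest.fixture
def aa_model():
    return RevModel.random(AMINO_ACIDS, seed=7)


def brute_force_log_likelihood(alignment: ResidueAlignment, tree: LabeledTree,
                               model: RevModel, lengths) -> float:
    """Likelihood by explicit summation over all internal-state assignments."""
    K = model.K
    codes = alignment.codes()
    row = {name: i for i, name in enumerate(alignment.taxon_names)}
    internal = [v for v in range(tree.n_nodes) if not tree.is_leaf[v]]
    P = {}
    for v in range(tree.n_nodes):
        if v != tree.root:
            P[v] = model.transition_matrix(float(lengths[tree.labels[v]]))
    edges = [(tree.parent[v], v) for v in range(tree.n_nodes)
             if v != tree.root]
    assignments = np.array(
        list(itertools.product(range(K), repeat=len(internal))), dtype=int
    )
    pos = {v: i for i, v in enumerate(internal)}
    total = 0.0
    for site in range(alignment.n_sites):
        state = {}
        for v in range(tree.n_nodes):
            if tree.is_leaf[v]:
                state[v] = codes[row[tree.labels[v]], site]
        prob = model.frequencies[assignments[:, pos[tree.root]]].copy()
        for parent, child in edges:
            ps = assignments[:, pos[parent]]
            if tree.is_leaf[child]:
                cs = state[child]
                if cs < 0:      # missing data: sum over child states = 1
                    continue
                prob *= P[child][ps, cs]
            else:
                prob *= P[child][ps, assignments[:, pos[child]]]
        total += np.log(prob.sum())
    return float(total)
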