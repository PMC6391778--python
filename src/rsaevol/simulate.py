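"""Paired-channel sequence simulation with known ground truth.

Generates amino-acid and pseudo-amino-acid (RSA) alignments on a shared
topology so every pipeline stage can be exercised against a known answer:
root states are drawn from the model's stationary distribution and evolved
down each branch with ``P(t)``; the RSA channel may scale selected focal
branches by a rate multiplier ``f`` (f = 1 is the exchangeable null); the
numeric RSA profile is recovered from the simulated PAA alignment through
the representative-value inverse of the 20-category map, so re-encoding it
reproduces the PAA alignment exactly.  A site-class mixture variant supports
testing of the heterotachy fit.

Default conditions are a 6-taxon tree with 2,000 gap-free sites, branch
lengths drawn uniformly from [0.02, 0.12], and random reversible generating
models per channel; all randomness flows from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .encoding import decode_paa20
from .io import AMINO_ACIDS, LabeledTree, ResidueAlignment, RsaProfile
from .revmodel import RevModel

DEFAULT_N_TAXA = 6
DEFAULT_N_SITES = 2000
#: Generating branch lengths are drawn uniformly from this range
#: (substitutions/site), matching typical vertebrate protein-family trees
#: in which most branches are short.
LENGTH_RANGE = (0.02, 0.12)


@dataclass
class SimulationSpec:
    """Everything needed to generate one paired AA/PAA dataset.

    ``base_lengths`` maps branch labels to generating lengths (``None``
    draws them uniformly from ``LENGTH_RANGE``); ``focal_branches`` get
    their RSA-channel lengths multiplied by ``rsa_multiplier`` (f).  An
    optional heterotachy setting (class weights plus per-class length scale
    factors) makes sites evolve under a length mixture in both channels.
    """

    tree: LabeledTree | None = None
    n_taxa: int = DEFAULT_N_TAXA
    aa_model: RevModel | None = None
    paa_model: RevModel | None = None
    base_lengths: Mapping[str, float] | float | None = None
    focal_branches: Sequence[str] = ()
    rsa_multiplier: float = 1.0
    heterotachy_weights: Sequence[float] | None = None
    heterotachy_scales: Sequence[float] | None = None
    n_sites: int = DEFAULT_N_SITES
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rsa_multiplier <= 0:
            raise ValueError("rsa_multiplier must be positive")
        if (self.heterotachy_weights is None) != (self.heterotachy_scales is None):
            raise ValueError("heterotachy weights and scales go together")
        if self.heterotachy_weights is not None:
            w = np.asarray(self.heterotachy_weights, dtype=float)
            if (w < 0).any() or abs(w.sum() - 1) > 1e-9:
                raise ValueError("heterotachy weights must lie on the simplex")
            if len(self.heterotachy_scales) != w.size:
                raise ValueError("one scale per heterotachy class")


@dataclass
class PairedSimulation:
    aa_alignment: ResidueAlignment
    paa_alignment: ResidueAlignment
    rsa_profile: RsaProfile
    truth: dict = field(default_factory=dict)

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth, fh, indent=1)


# ---------------------------------------------------------------------------
# Topologies
# ---------------------------------------------------------------------------


def random_yule_tree(n_taxa: int, seed=None) -> LabeledTree:
    """A random Yule (pure-birth, unit-rate) topology with n_taxa leaves.

    Only the shape is used downstream (generating branch lengths are set
    separately); leaves are named ``t1..tn``.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    root: list = ["t1", "t2"]
    # (node, child-slot) of every extant tip; splitting a uniformly random
    # extant lineage at each event gives the Yule shape
    tips: list[tuple[list, int]] = [(root, 0), (root, 1)]
    for i in range(3, n_taxa + 1):
        k = int(rng.integers(len(tips)))
        node, slot = tips[k]
        child: list = [node[slot], f"t{i}"]
        node[slot] = child
        tips[k] = (child, 0)
        tips.append((child, 1))

    def serialize(node) -> str:
        if isinstance(node, str):
            return node
        return "(" + ",".join(serialize(c) for c in node) + ")"

    return LabeledTree.from_newick(serialize(root) + ";")


def _length_vector(tree: LabeledTree,
                   lengths: Mapping[str, float] | float | None,
                   rng: np.random.Generator) -> dict[str, float]:
    labels = tree.branch_labels
    if lengths is None:
        vals = rng.uniform(*LENGTH_RANGE, size=len(labels))
        return dict(zip(labels, map(float, vals)))
    if np.isscalar(lengths):
        return {lab: float(lengths) for lab in labels}
    missing = set(labels) - set(lengths)
    if missing:
        raise ValueError(f"no generating length for branches {sorted(missing)}")
    return {lab: float(lengths[lab]) for lab in labels}


# ---------------------------------------------------------------------------
# Core simulation
# ---------------------------------------------------------------------------


def _evolve(tree: LabeledTree, model: RevModel,
            lengths: Mapping[str, float], n_sites: int,
            rng: np.random.Generator) -> np.ndarray:
    """Simulate states for every node; returns (n_nodes, n_sites) codes."""
    K = model.K
    states = np.empty((tree.n_nodes, n_sites), dtype=np.int64)
    root = tree.root
    states[root] = rng.choice(K, size=n_sites, p=model.frequencies)
    for v in reversed(range(tree.n_nodes)):   # preorder
        for c in tree.children[v]:
            t = lengths[tree.labels[c]]
            if t < 0:
                raise ValueError(f"negative length on branch {tree.labels[c]}")
            P = model.transition_matrix(t)
            cum = P.cumsum(axis=1)
            u = rng.random(n_sites)
            states[c] = (u[:, None] > cum[states[v]]).sum(axis=1)
    return states


def _to_alignment(tree: LabeledTree, states: np.ndarray,
                  alphabet: str) -> ResidueAlignment:
    names, rows = [], []
    for v in range(tree.n_nodes):
        if tree.is_leaf[v]:
            names.append(tree.labels[v])
            rows.append("".join(alphabet[s] for s in states[v]))
    return ResidueAlignment(names, rows, alphabet, missing="-")


def simulate_alignment(tree: LabeledTree, model: RevModel,
                       lengths: Mapping[str, float] | float,
                       n_sites: int, seed=None) -> ResidueAlignment:
    """Simulate one gap-free alignment under a reversible model.

    Deterministic for a given seed (single PCG64 stream, fixed traversal
    order).
    """
    rng = np.random.default_rng(seed)
    lens = _length_vector(tree, lengths, rng)
    states = _evolve(tree, model, lens, n_sites, rng)
    return _to_alignment(tree, states, model.alphabet)


def simulate_heterotachy(tree: LabeledTree, model: RevModel,
                         class_lengths: Sequence[Mapping[str, float]],
                         weights: Sequence[float], n_sites: int,
                         seed=None) -> tuple[ResidueAlignment, np.ndarray]:
    """Simulate under a branch-length mixture; returns per-site class truth.

    Sites are assigned to classes by weight, then each class's sites evolve
    with that class's full branch-length set.
    """
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1) > 1e-9 or (w < 0).any():
        raise ValueError("weights must lie on the simplex")
    rng = np.random.default_rng(seed)
    assignment = rng.choice(len(w), size=n_sites, p=w)
    codes = np.empty((tree.n_nodes, n_sites), dtype=np.int64)
    for h, lens in enumerate(class_lengths):
        idx = np.nonzero(assignment == h)[0]
        if idx.size == 0:
            continue
        states = _evolve(tree, model, lens, idx.size, rng)
        codes[:, idx] = states
    return _to_alignment(tree, codes, model.alphabet), assignment


def simulate_paired(spec: SimulationSpec) -> PairedSimulation:
    """Simulate the AA and RSA channels of one protein family.

    Both channels share the topology; the PAA channel's generating lengths
    equal the base lengths except on focal branches, which are scaled by
    the multiplier f.  The returned RSA profile decodes the PAA letters to
    representative grid values, so encoding it reproduces the PAA channel
    exactly, and the truth record carries everything needed to score a
    downstream call.
    """
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree or random_yule_tree(
        spec.n_taxa, seed=int(rng.integers(2**31))
    )
    aa_model = spec.aa_model or RevModel.random(
        AMINO_ACIDS, seed=int(rng.integers(2**31))
    )
    paa_model = spec.paa_model or RevModel.random(
        AMINO_ACIDS, seed=int(rng.integers(2**31))
    )
    base = _length_vector(tree, spec.base_lengths, rng)
    unknown = set(spec.focal_branches) - set(tree.branch_labels)
    if unknown:
        raise ValueError(f"focal branches {sorted(unknown)} not in tree")
    paa_lengths = {
        lab: val * (spec.rsa_multiplier if lab in spec.focal_branches else 1.0)
        for lab, val in base.items()
    }

    def channel(model, lengths, seed):
        if spec.heterotachy_weights is None:
            return simulate_alignment(
                tree, model, lengths, spec.n_sites, seed=seed
            )
        class_lengths = [
            {lab: val * s for lab, val in lengths.items()}
            for s in spec.heterotachy_scales
        ]
        aln, _ = simulate_heterotachy(
            tree, model, class_lengths, spec.heterotachy_weights,
            spec.n_sites, seed=seed,
        )
        return aln

    aa_aln = channel(aa_model, base, int(rng.integers(2**31)))
    paa_aln = channel(paa_model, paa_lengths, int(rng.integers(2**31)))
    rsa_profile = decode_paa20(paa_aln)
    truth = {
        "focal_branches": list(spec.focal_branches),
        "rsa_multiplier": spec.rsa_multiplier,
        "base_lengths": base,
        "paa_lengths": paa_lengths,
        "n_sites": spec.n_sites,
        "seed": spec.seed,
        "newick": tree.to_newick(lengths=base),
    }
    return PairedSimulation(aa_aln, paa_aln, rsa_profile, truth)
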