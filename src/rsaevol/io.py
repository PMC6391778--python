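"""Core containers and file formats.

This module holds the three data structures the rest of the package is
built on -- :class:`ResidueAlignment`, :class:`LabeledTree` and
:class:`RsaProfile` -- together with readers and writers for the plain-text
formats they travel in: FASTA alignments, Newick topologies (with
deterministic internal-node labelling), tab-separated per-residue solvent
accessibility profiles, and NHX-annotated output trees.

Internal nodes are labelled ``N1, N2, ...`` in depth-first postorder so that
the same Newick file always yields the same branch labels; every downstream
table is keyed by these labels.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Amino-acid (and pseudo-amino-acid) alphabet in the ordering used by all
#: rate matrices in this package.  Note E precedes Q.
AMINO_ACIDS = "ARNDCEQGHILKMFPSTWYV"

#: Characters treated as missing data in alignments.
DEFAULT_MISSING = "-?X"

#: The legal grid of relative solvent accessibility values; -5 codes "unknown".
RSA_GRID = tuple(range(-5, 100, 5))

#: Sentinel stored in an RsaProfile at alignment gap positions.
GAP_VALUE = -100

#: Branch classification tags used in NHX output.
NHX_TAGS = ("accel", "decel", "neutral", "filtered")

_CALL_TO_TAG = {
    "accelerated": "accel",
    "decelerated": "decel",
    "neutral": "neutral",
    "filtered": "filtered",
}
_TAG_TO_CALL = {v: k for k, v in _CALL_TO_TAG.items()}


class AlignmentError(ValueError):
    """Malformed alignment (ragged rows, duplicate names, ...)."""


class AlphabetError(AlignmentError):
    """A symbol outside the declared alphabet plus missing-data characters."""


class TreeError(ValueError):
    """Malformed or mismatching tree input."""


class ProfileError(ValueError):
    """Malformed RSA profile input."""


# ---------------------------------------------------------------------------
# ResidueAlignment
# ---------------------------------------------------------------------------


@dataclass
class ResidueAlignment:
    """A gapped alignment over a declared K-letter alphabet.

    Parameters
    ----------
    taxon_names:
        Unique sequence identifiers, in file order.
    rows:
        One symbol string per taxon; all the same length.
    alphabet:
        Ordered string of the K legal residue symbols.
    missing:
        Characters treated as missing data (gaps and unknowns).
    """

    taxon_names: list[str]
    rows: list[str]
    alphabet: str = AMINO_ACIDS
    missing: str = DEFAULT_MISSING

    def __post_init__(self) -> None:
        if len(self.taxon_names) != len(self.rows):
            raise AlignmentError("taxon_names and rows differ in length")
        if len(set(self.taxon_names)) != len(self.taxon_names):
            raise AlignmentError("duplicate taxon names")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise AlphabetError("alphabet contains repeated symbols")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError(
                f"rows have unequal lengths: {sorted(lengths)}"
            )
        self._validate_symbols()

    def _validate_symbols(self) -> None:
        legal = set(self.alphabet) | set(self.missing)
        for name, row in zip(self.taxon_names, self.rows):
            for pos, ch in enumerate(row):
                if ch not in legal:
                    raise AlphabetError(
                        f"symbol {ch!r} at {name}:{pos} is outside the "
                        f"alphabet {self.alphabet!r} and missing set "
                        f"{self.missing!r}"
                    )

    # -- basic geometry ----------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    # -- numeric views -----------------------------------------------------

    def codes(self) -> np.ndarray:
        """Integer matrix (n_taxa, n_sites); alphabet index, -1 for missing."""
        cached = self.__dict__.get("_codes")
        if cached is not None:
            return cached
        lut = np.full(256, -2, dtype=np.int16)
        for ch in self.missing:
            lut[ord(ch)] = -1
        for i, ch in enumerate(self.alphabet):
            lut[ord(ch)] = i
        mat = np.empty((self.n_taxa, self.n_sites), dtype=np.int16)
        for r, row in enumerate(self.rows):
            mat[r] = lut[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]
        self.__dict__["_codes"] = mat
        return mat

    def gap_mask(self) -> np.ndarray:
        """Boolean matrix, True where the symbol is missing."""
        return self.codes() == -1

    def select_columns(self, index: Sequence[int]) -> "ResidueAlignment":
        """New alignment restricted to the given column indices (in order)."""
        idx = np.asarray(index, dtype=int)
        rows = ["".join(row[i] for i in idx) for row in self.rows]
        return ResidueAlignment(
            list(self.taxon_names), rows, self.alphabet, self.missing
        )

    # -- i/o -----------------------------------------------------------------

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(row), id=name, description="")
            for name, row in zip(self.taxon_names, self.rows)
        ]
        SeqIO.write(records, str(path), "fasta")

    def __eq__(self, other) -> bool:  # codes cache must not affect equality
        if not isinstance(other, ResidueAlignment):
            return NotImplemented
        return (
            self.taxon_names == other.taxon_names
            and self.rows == other.rows
            and self.alphabet == other.alphabet
            and self.missing == other.missing
        )


def read_fasta(path, alphabet: str | None = None,
               missing: str = DEFAULT_MISSING) -> ResidueAlignment:
    """Read a gapped FASTA alignment.

    ``alphabet=None`` uses the standard 20-letter set; ``alphabet="infer"``
    derives the alphabet from the symbols present (sorted); any other string
    is taken verbatim.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    names = [r.id for r in records]
    rows = [str(r.seq) for r in records]
    if alphabet == "infer":
        symbols = sorted({c for row in rows for c in row} - set(missing))
        alphabet = "".join(symbols)
    elif alphabet is None:
        alphabet = AMINO_ACIDS
    return ResidueAlignment(names, rows, alphabet, missing)


# ---------------------------------------------------------------------------
# LabeledTree
# ---------------------------------------------------------------------------


class LabeledTree:
    """A fixed, labelled topology stored in postorder arrays.

    Nodes are indexed ``0 .. n_nodes-1`` in depth-first postorder; the root is
    the last index.  Every non-root node identifies the branch above it, so a
    branch is referred to by its child node's label (the taxon name for leaf
    branches, the ``N<k>``-style label for internal branches).
    """

    def __init__(self, parent: np.ndarray, children: list[list[int]],
                 labels: list[str], is_leaf: np.ndarray,
                 input_lengths: dict[str, float] | None = None,
                 polytomies: tuple[str, ...] = ()):
        self.parent = parent
        self.children = children
        self.labels = labels
        self.is_leaf = is_leaf
        self.input_lengths = input_lengths or {}
        self.polytomies = polytomies
        self.label_to_node = {lab: i for i, lab in enumerate(labels)}
        if len(self.label_to_node) != len(labels):
            raise TreeError("node labels are not unique")

    # -- construction --------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str,
                    leaf_names: Iterable[str] | None = None) -> "LabeledTree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        return cls.from_dendropy(dtree, leaf_names)

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree",
                      leaf_names: Iterable[str] | None = None) -> "LabeledTree":
        nodes = list(dtree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        children: list[list[int]] = [[] for _ in range(n)]
        labels: list[str] = [""] * n
        is_leaf = np.zeros(n, dtype=bool)
        input_lengths: dict[str, float] = {}
        k = 0
        for i, nd in enumerate(nodes):
            kids = nd.child_nodes()
            if not kids:
                is_leaf[i] = True
                if nd.taxon is None or not nd.taxon.label:
                    raise TreeError("unnamed leaf in Newick input")
                labels[i] = nd.taxon.label
            else:
                k += 1
                labels[i] = nd.label if nd.label else f"N{k}"
                for ch in kids:
                    j = index[id(ch)]
                    parent[j] = i
                    children[i].append(j)
        root = n - 1
        # a trifurcating root is the conventional unrooted representation,
        # so it is not flagged; any other >2-way split is
        polys = tuple(
            labels[i]
            for i in range(n)
            if len(children[i]) > (3 if i == root else 2)
        )
        if polys:
            warnings.warn(
                f"polytomies at nodes {polys}; branch statistics treat each "
                "child branch independently", stacklevel=2,
            )
        for i, nd in enumerate(nodes):
            if i != root and nd.edge.length is not None:
                input_lengths[labels[i]] = float(nd.edge.length)
        tree = cls(parent, children, labels, is_leaf,
                   input_lengths, polys)
        if leaf_names is not None:
            expected = set(leaf_names)
            got = set(tree.leaf_names)
            if expected != got:
                raise TreeError(
                    f"leaf set mismatch: tree-only={sorted(got - expected)}, "
                    f"expected-only={sorted(expected - got)}"
                )
        return tree

    # -- geometry -------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def leaf_names(self) -> list[str]:
        return [self.labels[i] for i in range(self.n_nodes) if self.is_leaf[i]]

    @property
    def branch_labels(self) -> list[str]:
        """Labels of every branch (all non-root nodes), postorder."""
        return [self.labels[i] for i in range(self.n_nodes) if i != self.root]

    @property
    def inner_branch_labels(self) -> list[str]:
        """Labels of internal branches (non-leaf, non-root nodes)."""
        return [
            self.labels[i]
            for i in range(self.n_nodes)
            if not self.is_leaf[i] and i != self.root
        ]

    # -- serialisation ----------------------------------------------------------

    def to_newick(self, lengths: Mapping[str, float] | None = None,
                  tags: Mapping[str, str] | None = None) -> str:
        """Serialise, optionally with branch lengths and NHX ``rsa=`` tags."""

        def fmt(i: int) -> str:
            lab = self.labels[i]
            if self.is_leaf[i]:
                s = lab
            else:
                s = "(" + ",".join(fmt(c) for c in self.children[i]) + ")" + lab
            if i != self.root:
                if lengths is not None and lab in lengths:
                    s += f":{lengths[lab]:.10g}"
                elif lengths is None and lab in self.input_lengths:
                    s += f":{self.input_lengths[lab]:.10g}"
            if tags is not None and lab in tags:
                s += f"[&&NHX:rsa={tags[lab]}]"
            return s

        return fmt(self.root) + ";"


def read_newick(path, leaf_names: Iterable[str] | None = None) -> LabeledTree:
    """Read a Newick topology and label its internal nodes deterministically.

    Existing internal labels are preserved; unlabelled internal nodes get
    ``N<k>`` where k is the node's 1-based index among internal nodes in
    depth-first postorder.  If ``leaf_names`` is given the leaf set must
    match it exactly.
    """
    with open(path) as fh:
        return LabeledTree.from_newick(fh.read(), leaf_names)


# ---------------------------------------------------------------------------
# RSA profiles
# ---------------------------------------------------------------------------


@dataclass
class RsaProfile:
    """Per-taxon, per-alignment-column RSA values on the 5-unit grid.

    ``values`` has shape (n_taxa, n_sites); gap positions hold
    :data:`GAP_VALUE`, every other cell is a grid value in [-5, 95]
    (-5 codes "unknown").
    """

    taxon_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.taxon_names):
            raise ProfileError("values must be (n_taxa, n_sites)")
        body = self.values[self.values != GAP_VALUE]
        bad = body[(body < -5) | (body > 95) | (body % 5 != 0)]
        if bad.size:
            raise ProfileError(
                f"RSA value {int(bad[0])} is off the grid -5..95 step 5"
            )

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    def residue_values(self, taxon: str) -> np.ndarray:
        """The non-gap values of one taxon, in column order."""
        row = self.values[self.taxon_names.index(taxon)]
        return row[row != GAP_VALUE]

    def select_columns(self, index: Sequence[int]) -> "RsaProfile":
        idx = np.asarray(index, dtype=int)
        return RsaProfile(list(self.taxon_names), self.values[:, idx])


def read_rsa_profile(path, alignment: ResidueAlignment) -> RsaProfile:
    """Read a TSV of per-residue RSA values and map them onto the alignment.

    Each line is ``taxon<TAB>v1<TAB>v2...`` with one integer per *non-gap*
    residue of that taxon; the values are placed at the taxon's non-gap
    alignment columns in order, gap columns are skipped.
    """
    per_taxon: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            name = parts[0]
            try:
                vals = [int(tok) for tok in parts[1:] if tok != ""]
            except ValueError as exc:
                raise ProfileError(
                    f"line {lineno}: non-integer RSA value ({exc})"
                ) from None
            per_taxon[name] = vals
    return profile_from_residue_values(alignment, per_taxon)


def profile_from_residue_values(
    alignment: ResidueAlignment, per_taxon: Mapping[str, Sequence[int]]
) -> RsaProfile:
    """Place per-residue value lists onto alignment coordinates."""
    missing = set(alignment.taxon_names) - set(per_taxon)
    if missing:
        raise ProfileError(f"no RSA values for taxa {sorted(missing)}")
    gaps = alignment.gap_mask()
    values = np.full((alignment.n_taxa, alignment.n_sites), GAP_VALUE, dtype=int)
    for r, name in enumerate(alignment.taxon_names):
        vals = np.asarray(per_taxon[name], dtype=int)
        cols = np.nonzero(~gaps[r])[0]
        if vals.size != cols.size:
            raise ProfileError(
                f"{name}: {vals.size} RSA values for {cols.size} non-gap "
                "residues"
            )
        values[r, cols] = vals
    return RsaProfile(list(alignment.taxon_names), values)


def write_rsa_profile(profile: RsaProfile, path) -> None:
    """Write the per-residue TSV dialect read by :func:`read_rsa_profile`."""
    with open(path, "w") as fh:
        for name in profile.taxon_names:
            vals = profile.residue_values(name)
            fh.write(name + "\t" + "\t".join(str(int(v)) for v in vals) + "\n")


# ---------------------------------------------------------------------------
# Annotated (NHX) trees
# ---------------------------------------------------------------------------


def write_annotated_tree(tree: LabeledTree, calls: Mapping[str, str], path,
                         lengths: Mapping[str, float] | None = None) -> None:
    """Write the topology with per-branch NHX ``rsa=`` classification tags.

    ``calls`` maps inner-branch labels to
    ``accelerated|decelerated|neutral|filtered`` (the short NHX tags are also
    accepted).  Unknown branch labels raise :class:`TreeError`.
    """
    known = set(tree.inner_branch_labels)
    tags: dict[str, str] = {}
    for label, call in calls.items():
        if label not in known:
            raise TreeError(f"unknown inner branch label {label!r}")
        tag = _CALL_TO_TAG.get(call, call)
        if tag not in NHX_TAGS:
            raise TreeError(f"unknown classification {call!r}")
        tags[label] = tag
    with open(path, "w") as fh:
        fh.write(tree.to_newick(lengths=lengths, tags=tags) + "\n")


_NHX_RE = re.compile(
    r"\)([^\s(),:\[\]]+)(?::[0-9.eE+\-]+)?\[&&NHX:rsa=([a-z]+)\]"
)


def read_annotated_tree(path) -> tuple[LabeledTree, dict[str, str]]:
    """Parse back an NHX-annotated tree; returns (tree, label -> call)."""
    with open(path) as fh:
        text = fh.read()
    calls = {
        m.group(1): _TAG_TO_CALL[m.group(2)]
        for m in _NHX_RE.finditer(text)
        if m.group(2) in _TAG_TO_CALL
    }
    stripped = re.sub(r"\[&&NHX[^\]]*\]", "", text)
    tree = LabeledTree.from_newick(stripped)
    return tree, calls
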