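"""Phylogenetic likelihood engine on a fixed topology.

Implements Felsenstein pruning over compressed site patterns, per-branch
length optimisation, a heterotachy mixture in which every class carries its
own full set of branch lengths (and optionally its own frequency vector),
and an edge-unlinked site-partition model driven by a site-diversity
categorisation.

Transition probabilities come from the spectral decomposition of the
reversible rate matrix (symmetrised through pi^(1/2)), so ``P(t)`` along a
branch costs a couple of small matrix products.  Branch lengths live in
``[BRANCH_MIN, BRANCH_MAX]``; per-branch objectives are maximised with a
safeguarded Newton iteration on the spectral form of the likelihood, which
evaluates the site likelihood of a single branch as
``sum_k coef_k * exp(lam_k * t)`` and therefore supports first and second
derivatives essentially for free.  All classes of a mixture are swept
jointly as stacked arrays.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import _kernels
from .io import AlignmentError, LabeledTree, ResidueAlignment
from .revmodel import RevModel, empirical_frequencies

BRANCH_MIN = 1e-6
BRANCH_MAX = 10.0

_TINY = 1e-300
_RESCALE_THRESHOLD = 1e-240


class LikelihoodError(ArithmeticError):
    """Non-finite likelihood; carries the offending site index."""

    def __init__(self, message: str, site: int | None = None):
        super().__init__(message)
        self.site = site


# ---------------------------------------------------------------------------
# Fit result containers
# ---------------------------------------------------------------------------


@dataclass
class BranchLengthFit:
    lengths: dict[str, float]
    log_likelihood: float
    converged: bool
    n_sweeps: int


@dataclass
class HeterotachyFit:
    """Mixture fit with class-specific branch-length sets.

    Classes are sorted by total tree length (ascending), which fixes the
    otherwise arbitrary class labelling.  ``combined_lengths`` is the
    weight-averaged per-branch length, the expected evolved distance under
    the mixture.
    """

    n_classes: int
    weights: np.ndarray
    class_lengths: list[dict[str, float]]
    class_frequencies: list[np.ndarray]
    log_likelihood: float
    combined_lengths: dict[str, float]
    frozen_classes: tuple[int, ...] = ()
    converged: bool = True
    n_iter: int = 0

    def class_tree_lengths(self) -> np.ndarray:
        return np.array([sum(d.values()) for d in self.class_lengths])

    def to_json_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "weights": [float(w) for w in self.weights],
            "class_lengths": self.class_lengths,
            "class_frequencies": [
                [float(x) for x in f] for f in self.class_frequencies
            ],
            "log_likelihood": float(self.log_likelihood),
            "combined_lengths": self.combined_lengths,
            "frozen_classes": list(self.frozen_classes),
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


@dataclass
class PartitionFit:
    """Edge-unlinked site-partition fit.

    ``site_categories`` is the (possibly merged) per-site category id;
    ``combined_lengths`` weights each category's branch length by its
    fraction of sites.
    """

    site_categories: np.ndarray
    category_lengths: dict[int, dict[str, float]]
    category_frequencies: dict[int, np.ndarray]
    category_log_likelihoods: dict[int, float]
    log_likelihood: float
    site_fractions: dict[int, float]
    combined_lengths: dict[str, float]
    merged: dict[int, int] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "site_categories": [int(c) for c in self.site_categories],
            "category_lengths": {
                str(k): v for k, v in self.category_lengths.items()
            },
            "category_frequencies": {
                str(k): [float(x) for x in v]
                for k, v in self.category_frequencies.items()
            },
            "category_log_likelihoods": {
                str(k): float(v)
                for k, v in self.category_log_likelihoods.items()
            },
            "log_likelihood": float(self.log_likelihood),
            "site_fractions": {
                str(k): float(v) for k, v in self.site_fractions.items()
            },
            "combined_lengths": self.combined_lengths,
            "merged": {str(k): int(v) for k, v in self.merged.items()},
        }


# ---------------------------------------------------------------------------
# Pattern-compressed pruning core
# ---------------------------------------------------------------------------


class AlignmentLikelihood:
    """Reusable pruning machinery for one (alignment, tree) pair.

    Compresses alignment columns into unique site patterns once and exposes
    likelihood evaluation and branch-length optimisation for a stack of H
    model classes sharing the topology.  A single-model fit is the H=1 case.
    """

    def __init__(self, alignment: ResidueAlignment, tree: LabeledTree):
        if set(alignment.taxon_names) != set(tree.leaf_names):
            raise AlignmentError(
                "alignment taxa do not match tree leaves"
            )
        self.alignment = alignment
        self.tree = tree
        self.K = len(alignment.alphabet)
        codes = alignment.codes()
        pats, inverse, counts = np.unique(
            codes, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = pats                       # (n_taxa, n_pat)
        self.pattern_of_site = inverse.ravel()
        self.pattern_weights = counts.astype(float)
        self.n_pat = pats.shape[1]
        # one-hot leaf partials; missing -> all ones
        n = tree.n_nodes
        row_of = {name: i for i, name in enumerate(alignment.taxon_names)}
        self._leaf_partial: dict[int, np.ndarray] = {}
        for v in range(n):
            if tree.is_leaf[v]:
                col = pats[row_of[tree.labels[v]]]
                part = np.zeros((1, self.n_pat, self.K))
                ok = col >= 0
                part[0, ok, col[ok]] = 1.0
                part[0, ~ok, :] = 1.0
                self._leaf_partial[v] = part
        # per-pattern symbol counts, for mixture frequency updates
        counts_mat = np.zeros((self.n_pat, self.K))
        for r in range(pats.shape[0]):
            col = pats[r]
            ok = col >= 0
            np.add.at(counts_mat, (np.nonzero(ok)[0], col[ok]), 1.0)
        self.pattern_symbol_counts = counts_mat
        self._order = range(n)  # nodes are already postorder-indexed
        # per-node underflow rescaling only pays off on larger trees; small
        # trees cannot underflow double precision and skip the max() scans
        self._rescale = n > 25
        # flattened topology arrays for the compiled kernels
        self._is_leaf = np.asarray(tree.is_leaf, dtype=np.bool_)
        offs = np.zeros(n + 1, dtype=np.int64)
        flat: list[int] = []
        for v in range(n):
            flat.extend(tree.children[v])
            offs[v + 1] = len(flat)
        self._ch_off = offs
        self._ch_flat = np.asarray(flat, dtype=np.int64)
        leafD = np.zeros((n, self.n_pat, self.K))
        for v, part in self._leaf_partial.items():
            leafD[v] = part[0]
        self._leafD = leafD
        self._max_children = int(np.diff(offs).max()) if n > 1 else 0
        self._use_kernels = _kernels.HAVE_NUMBA and self._max_children <= 8
        # with a bifurcating root only the sum of the two root-adjacent
        # lengths is identifiable (pulley principle); the optimiser splits
        # it equally, which is likelihood-preserving and keeps both
        # branches' statistics stable
        root_kids = tree.children[tree.root]
        self._root_pair = tuple(root_kids) if len(root_kids) == 2 else None

    # -- model stack ---------------------------------------------------------

    def set_models(self, models: Sequence[RevModel]) -> None:
        H, K = len(models), self.K
        self._lam = np.empty((H, K))
        self._R = np.empty((H, K, K))
        self._L = np.empty((H, K, K))
        self._pi = np.empty((H, K))
        for h, m in enumerate(models):
            if m.K != K:
                raise AlignmentError(
                    f"model alphabet size {m.K} does not match alignment ({K})"
                )
            lam, R, L = m.eigensystem()
            self._lam[h], self._R[h], self._L[h] = lam, R, L
            self._pi[h] = m.frequencies
        self._Lt = self._L.transpose(0, 2, 1)

    @property
    def n_classes(self) -> int:
        return self._lam.shape[0]

    def _P(self, t: np.ndarray) -> np.ndarray:
        """Stacked transition matrices for per-class lengths t of one edge."""
        E = np.exp(self._lam * np.asarray(t)[:, None])      # (H, K)
        return (self._R * E[:, None, :]) @ self._L

    # -- length bookkeeping ----------------------------------------------------

    def lengths_vector(self, lengths: Mapping[str, float] | float | None,
                       H: int = 1) -> np.ndarray:
        """(H, n_nodes) length array from a label->length mapping or scalar."""
        tree = self.tree
        vec = np.full(tree.n_nodes, 0.1)
        if lengths is None:
            pass
        elif np.isscalar(lengths):
            vec[:] = float(lengths)
        else:
            for lab, val in lengths.items():
                vec[tree.label_to_node[lab]] = float(val)
        vec[tree.root] = 0.0
        out = np.tile(vec, (H, 1))
        np.clip(out[:, : tree.root], BRANCH_MIN, BRANCH_MAX,
                out=out[:, : tree.root])
        return out

    def lengths_dict(self, vec: np.ndarray) -> dict[str, float]:
        tree = self.tree
        return {
            tree.labels[i]: float(vec[i])
            for i in range(tree.n_nodes)
            if i != tree.root
        }

    # -- likelihood ------------------------------------------------------------

    def _down(self, lengths: np.ndarray):
        """Postorder partials; returns (D, scaleD) indexed by node."""
        if self._use_kernels:
            return _kernels.down_pass(
                self._is_leaf, self._ch_off, self._ch_flat, self._leafD,
                self._lam, self._R, self._L, lengths, self._rescale,
            )
        tree = self.tree
        D: list[np.ndarray | None] = [None] * tree.n_nodes
        S: list = [0.0] * tree.n_nodes
        rescale = self._rescale
        for v in self._order:
            if tree.is_leaf[v]:
                D[v] = self._leaf_partial[v]
                S[v] = 0.0
                continue
            prod = None
            scale = 0.0
            for c in tree.children[v]:
                M = D[c] @ self._P(lengths[:, c]).transpose(0, 2, 1)
                prod = M if prod is None else prod * M
                scale = scale + S[c]
            if rescale:
                m = prod.max(axis=2)
                if (m < _RESCALE_THRESHOLD).any():
                    div = np.where(m > 0, m, 1.0)
                    prod = prod / div[..., None]
                    scale = scale + np.log(div)
            D[v] = prod
            S[v] = scale
        return D, S

    def class_site_log_likelihood(self, lengths: np.ndarray,
                                  down=None) -> np.ndarray:
        """(H, n_pat) per-pattern log-likelihoods, one row per class."""
        D, S = down if down is not None else self._down(lengths)
        root = self.tree.root
        f = (D[root] * self._pi[:, None, :]).sum(axis=2)
        if down is None and not self._rescale and (f <= 0).any():
            # underflow on a nominally small tree: redo with rescaling on
            self._rescale = True
            return self.class_site_log_likelihood(lengths)
        ll = np.log(np.maximum(f, _TINY)) + S[root]
        return ll

    def log_likelihood(self, model: RevModel,
                       lengths: np.ndarray | Mapping[str, float]) -> float:
        self.set_models([model])
        if not isinstance(lengths, np.ndarray):
            lengths = self.lengths_vector(lengths)
        ll = self.class_site_log_likelihood(lengths)[0]
        total = float(ll @ self.pattern_weights)
        if not np.isfinite(total):
            bad_pat = int(np.nonzero(~np.isfinite(ll))[0][0])
            site = int(np.nonzero(self.pattern_of_site == bad_pat)[0][0])
            raise LikelihoodError(
                f"non-finite site likelihood at site {site}", site=site
            )
        return total

    # -- per-edge spectral optimisation -----------------------------------------

    def _edge_objective(self, coef, ew, t):
        E = np.exp(self._lam * t[:, None])
        f = np.maximum((coef @ E[:, :, None])[..., 0], _TINY)
        return (ew * np.log(f)).sum(axis=1), f, E

    def _optimize_edge(self, coef: np.ndarray, ew: np.ndarray,
                       t0: np.ndarray) -> np.ndarray:
        """Maximise per-class sum of weighted log site likelihoods over t.

        Safeguarded Newton iteration; steps that would lower the objective
        are halved back toward the current point, and lengths stay clamped
        to the branch bounds.
        """
        lam = self._lam
        t = np.clip(t0, BRANCH_MIN, BRANCH_MAX)
        q, f, E = self._edge_objective(coef, ew, t)
        active = ew.sum(axis=1) > 0
        for _ in range(8):
            lamE = lam * E
            f1 = (coef @ lamE[:, :, None])[..., 0]
            f2 = (coef @ (lam * lamE)[:, :, None])[..., 0]
            r1 = f1 / f
            g = (ew * r1).sum(axis=1)
            h = (ew * (f2 / f - r1 * r1)).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                newton = -g / h
            fallback = np.sign(g) * np.maximum(0.25 * t, 1e-4)
            step = np.where(h < -_TINY, newton, fallback)
            step = np.clip(step, -3.0, 3.0)
            step = np.where(active, step, 0.0)
            tn = np.clip(t + step, BRANCH_MIN, BRANCH_MAX)
            qn, fn, En = self._edge_objective(coef, ew, tn)
            for _ in range(12):
                worse = qn < q - 1e-12
                if not worse.any():
                    break
                tn = np.where(worse, 0.5 * (tn + t), tn)
                qn, fn, En = self._edge_objective(coef, ew, tn)
            accept = qn >= q - 1e-12
            moved = np.where(accept, np.abs(tn - t), 0.0)
            t = np.where(accept, tn, t)
            q = np.where(accept, qn, q)
            f = np.where(accept[:, None], fn, f)
            E = np.where(accept[:, None], En, E)
            if (moved < 1e-6 * (1.0 + t)).all():
                break
        return t

    def sweep(self, lengths: np.ndarray, ew: np.ndarray, down=None,
              process_edge: np.ndarray | None = None,
              need_below: np.ndarray | None = None):
        """One coordinate sweep over branches, all classes jointly.

        ``ew`` (H, n_pat) are effective pattern weights (pattern counts for a
        plain fit, responsibility-weighted counts inside EM).  ``down`` may
        carry a precomputed postorder pass for the current lengths.
        ``process_edge``/``need_below`` restrict the sweep to a subset of
        edges (compiled path only; used to skip quiescent branches late in
        EM).  Lengths are updated in place; returns ``(lengths, moves)``
        where ``moves`` is the per-edge length change (or None on the
        reference path).
        """
        if down is None:
            down = self._down(lengths)
        if self._use_kernels:
            n = self.tree.n_nodes
            if process_edge is None:
                process_edge = np.ones(n, dtype=np.bool_)
            if need_below is None:
                need_below = np.ones(n, dtype=np.bool_)
            moves = _kernels.sweep_pass(
                self._is_leaf, self._ch_off, self._ch_flat, self._pi,
                self._lam, self._R, self._L, self._leafD, lengths, ew,
                BRANCH_MIN, BRANCH_MAX, self._rescale, down[0],
                process_edge, need_below,
            )
            self._equalize_root_pair(lengths)
            return lengths, moves
        tree = self.tree
        D, S = down
        H = lengths.shape[0]
        root = tree.root
        rescale = self._rescale
        A: list[np.ndarray | None] = [None] * tree.n_nodes
        A[root] = np.broadcast_to(
            self._pi[:, None, :], (H, self.n_pat, self.K)
        )
        for v in reversed(range(tree.n_nodes)):   # preorder
            if tree.is_leaf[v]:
                continue
            kids = tree.children[v]
            Ms = {
                c: D[c] @ self._P(lengths[:, c]).transpose(0, 2, 1)
                for c in kids
            }
            for c in kids:
                U = A[v]
                for s in kids:
                    if s is not c:
                        U = U * Ms[s]
                coef = (U @ self._R) * (D[c] @ self._Lt)
                lengths[:, c] = self._optimize_edge(coef, ew, lengths[:, c])
                P = self._P(lengths[:, c])
                Ms[c] = D[c] @ P.transpose(0, 2, 1)
                if not tree.is_leaf[c]:
                    Ac = U @ P
                    if rescale:
                        m = Ac.max(axis=2)
                        if (m < _RESCALE_THRESHOLD).any():
                            div = np.where(m > 0, m, 1.0)
                            Ac = Ac / div[..., None]
                    A[c] = Ac
        self._equalize_root_pair(lengths)
        return lengths, None

    def _equalize_root_pair(self, lengths: np.ndarray) -> None:
        if self._root_pair is None:
            return
        c1, c2 = self._root_pair
        half = 0.5 * (lengths[:, c1] + lengths[:, c2])
        lengths[:, c1] = half
        lengths[:, c2] = half


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def tree_log_likelihood(alignment: ResidueAlignment, tree: LabeledTree,
                        model: RevModel,
                        lengths: Mapping[str, float] | float | None = None,
                        ) -> float:
    """Pruning log-likelihood of the alignment for fixed branch lengths.

    ``lengths`` maps branch labels to lengths (a scalar applies everywhere;
    ``None`` uses the lengths read from the input Newick).  Gaps and unknown
    residues contribute all-ones partials.
    """
    lik = AlignmentLikelihood(alignment, tree)
    if lengths is None:
        lengths = tree.input_lengths
    return lik.log_likelihood(model, lik.lengths_vector(lengths))


def optimize_branch_lengths(alignment: ResidueAlignment, tree: LabeledTree,
                            model: RevModel, *,
                            init: Mapping[str, float] | float | None = 0.1,
                            tol: float = 1e-4, max_sweeps: int = 100,
                            _likelihood: AlignmentLikelihood | None = None,
                            ) -> BranchLengthFit:
    """Maximise the likelihood over branch lengths, one branch at a time.

    Repeated coordinate sweeps run until the log-likelihood gain drops below
    ``tol``; lengths are clamped to ``[BRANCH_MIN, BRANCH_MAX]``.  The sweep
    never decreases the objective, so the optimum is at least as good as the
    starting point.
    """
    lik = _likelihood or AlignmentLikelihood(alignment, tree)
    lik.set_models([model])
    lengths = lik.lengths_vector(init)
    ew = lik.pattern_weights[None, :]
    down = lik._down(lengths)
    logL = float(
        lik.class_site_log_likelihood(lengths, down=down)[0]
        @ lik.pattern_weights
    )
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        lengths, _ = lik.sweep(lengths, ew, down=down)
        down = lik._down(lengths)
        new = float(
            lik.class_site_log_likelihood(lengths, down=down)[0]
            @ lik.pattern_weights
        )
        gain = new - logL
        logL = new
        if gain < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"branch-length optimisation did not converge in {max_sweeps} "
            "sweeps; returning best lengths found", stacklevel=2,
        )
    return BranchLengthFit(
        lik.lengths_dict(lengths[0]), logL, converged, sweeps
    )


def fit_heterotachy(alignment: ResidueAlignment, tree: LabeledTree,
                    model: RevModel, H: int = 3, *,
                    tol: float = 1e-3, max_iter: int = 200,
                    unlinked_frequencies: bool = True,
                    pseudocount: float = 0.5,
                    collapse_tol: float = 1e-4,
                    warm_start: "HeterotachyFit | None" = None,
                    sweeps_per_iter: int = 2,
                    _likelihood: AlignmentLikelihood | None = None,
                    ) -> HeterotachyFit:
    """Fit an H-class branch-length mixture (GHOST-style heterotachy).

    Each class carries its own full branch-length set and (by default) its
    own frequency vector; exchangeabilities are shared with the supplied
    family model.  Classes start from the single-set optimum with lengths
    scaled by a geometric ladder ({0.5, 1, 2} for H=3) and uniform weights;
    EM weight updates alternate with ``sweeps_per_iter`` joint branch sweeps
    per class until the log-likelihood gain falls below ``tol``, with a
    guarded step-doubling extrapolation along the EM direction.  Frequency
    updates are responsibility-weighted empirical counts, accepted only when
    they do not lower the mixture likelihood.  A class whose weight falls
    below ``collapse_tol`` is frozen and reported.

    H=1 reduces exactly to :func:`optimize_branch_lengths`.  A previous fit
    on closely related data (e.g. the full alignment, when fitting jackknife
    replicates) may be passed as ``warm_start``; its class lengths, weights
    and frequencies replace the initialisation ladder and the preliminary
    single-set fit, while EM still runs to the same tolerance.
    """
    if H < 1:
        raise ValueError("H must be >= 1")
    lik = _likelihood or AlignmentLikelihood(alignment, tree)
    s_matrix = model.exchangeabilities
    base = None
    if warm_start is None:
        base = optimize_branch_lengths(
            alignment, tree, model, _likelihood=lik
        )
        if H == 1:
            return HeterotachyFit(
                n_classes=1,
                weights=np.array([1.0]),
                class_lengths=[base.lengths],
                class_frequencies=[model.frequencies.copy()],
                log_likelihood=base.log_likelihood,
                combined_lengths=dict(base.lengths),
                converged=base.converged,
                n_iter=base.n_sweeps,
            )
        scales = 2.0 ** np.linspace(-1.0, 1.0, H)
        base_vec = lik.lengths_vector(base.lengths)[0]
        lengths = np.clip(
            base_vec[None, :] * scales[:, None], BRANCH_MIN, BRANCH_MAX
        )
        freqs = [model.frequencies.copy() for _ in range(H)]
        w = np.full(H, 1.0 / H)
    else:
        if warm_start.n_classes != H:
            raise ValueError("warm_start class count does not match H")
        lengths = np.stack([
            lik.lengths_vector(d)[0] for d in warm_start.class_lengths
        ])
        freqs = [np.asarray(f, dtype=float).copy()
                 for f in warm_start.class_frequencies]
        w = np.clip(np.asarray(warm_start.weights, dtype=float), 1e-3, None)
        w = w / w.sum()
    lengths[:, tree.root] = 0.0
    models = [RevModel(s_matrix, f, model.alphabet) for f in freqs]
    lik.set_models(models)
    wpat = lik.pattern_weights
    total_w = wpat.sum()
    frozen = np.zeros(H, dtype=bool)

    def mixture(sll_arr, w_arr):
        lw = np.log(np.maximum(w_arr, _TINY))[:, None] + sll_arr
        m = lw.max(axis=0)
        mix = m + np.log(np.exp(lw - m).sum(axis=0))
        return mix, np.exp(lw - mix)

    prev = -np.inf
    n_iter = 0
    converged = False
    down = lik._down(lengths)
    sll = lik.class_site_log_likelihood(lengths, down=down)
    # lazy scheduling: branches (and frequency vectors) that stopped moving
    # are skipped between periodic full passes; every skipped update would
    # have contributed less than the convergence tolerance anyway
    move_tol = 3e-4
    freq_tol = 1e-5
    last_move: np.ndarray | None = None
    freq_quiet = False
    n_nodes = tree.n_nodes
    for n_iter in range(1, max_iter + 1):
        # inner EM on the weights alone: cheap (no tree passes), and the
        # weight coordinate is the slowest-mixing one
        for _ in range(60):
            mix, r = mixture(sll, w)
            ll = float(mix @ wpat)
            w_new = (r * wpat).sum(axis=1) / total_w
            w_next = np.where(frozen, w, w_new)
            mix2, _ = mixture(sll, w_next)
            w = w_next
            if float(mix2 @ wpat) - ll < 0.1 * tol:
                break
        mix, r = mixture(sll, w)
        ll = float(mix @ wpat)
        if ll - prev < tol and n_iter > 1:
            converged = True
            break
        prev = ll
        frozen |= (w < collapse_tol) & ~frozen
        ew = r * wpat
        ew[frozen] = 0.0
        full_pass = (
            last_move is None or n_iter % 6 == 0 or not lik._use_kernels
        )
        proc = nb = None
        if not full_pass:
            # focus the sweep on the edges that are still drifting; the
            # periodic full pass picks up any edge this leaves behind
            thresh = max(move_tol, 0.2 * float(last_move.max()))
            proc = last_move > thresh
            nb = proc.copy()
            for v in range(n_nodes):           # postorder accumulation
                for c in tree.children[v]:
                    if proc[c] or nb[c]:
                        nb[v] = True
        lengths_prev = lengths.copy()
        freqs_prev = [f.copy() for f in freqs]
        for _ in range(sweeps_per_iter):
            lengths, moves = lik.sweep(lengths, ew, down=down,
                                       process_edge=proc, need_below=nb)
            down = lik._down(lengths)
            if moves is not None:
                last_move = moves
        sll = lik.class_site_log_likelihood(lengths, down=down)
        if unlinked_frequencies and (full_pass or not freq_quiet):
            cand = []
            delta_pi = 0.0
            for h in range(H):
                if frozen[h]:
                    cand.append(freqs[h])
                    continue
                counts = pseudocount + ew[h] @ lik.pattern_symbol_counts
                f_new = counts / counts.sum()
                delta_pi = max(delta_pi, float(np.abs(f_new - freqs[h]).max()))
                cand.append(f_new)
            freq_quiet = delta_pi < freq_tol
            if not freq_quiet:
                cand_models = [
                    RevModel(s_matrix, f, model.alphabet) for f in cand
                ]
                lik.set_models(cand_models)
                down_c = lik._down(lengths)
                sll_c = lik.class_site_log_likelihood(lengths, down=down_c)
                mix_c, _ = mixture(sll_c, w)
                mix_cur, _ = mixture(sll, w)
                if float(mix_c @ wpat) >= float(mix_cur @ wpat) - 1e-9:
                    freqs, models = cand, cand_models
                    sll, down = sll_c, down_c
                else:
                    lik.set_models(models)
        # step-doubling acceleration along the EM direction in (lengths,
        # frequencies) jointly; a longer step is kept only when it raises
        # the mixture likelihood
        len_step = lengths - lengths_prev
        frq_step = [f - fp for f, fp in zip(freqs, freqs_prev)]
        big_move = float(np.abs(len_step).max()) > 1e-8 or any(
            float(np.abs(d).max()) > 1e-10 for d in frq_step
        )
        if big_move:
            mix_now, _ = mixture(sll, w)
            ll_now = float(mix_now @ wpat)
            for _ in range(3):
                cand_len = np.clip(lengths + 2.0 * len_step,
                                   BRANCH_MIN, BRANCH_MAX)
                cand_len[:, tree.root] = 0.0
                cand_frq = [
                    np.maximum(f + 2.0 * d, 1e-8) for f, d in
                    zip(freqs, frq_step)
                ]
                cand_frq = [f / f.sum() for f in cand_frq]
                cand_models = [
                    RevModel(s_matrix, f, model.alphabet) for f in cand_frq
                ]
                lik.set_models(cand_models)
                down_e = lik._down(cand_len)
                sll_e = lik.class_site_log_likelihood(cand_len, down=down_e)
                mix_e, _ = mixture(sll_e, w)
                ll_e = float(mix_e @ wpat)
                if ll_e <= ll_now + 1e-12:
                    lik.set_models(models)
                    break
                len_step = cand_len - lengths
                frq_step = [cf - f for cf, f in zip(cand_frq, freqs)]
                lengths, sll, down, ll_now = cand_len, sll_e, down_e, ll_e
                freqs, models = cand_frq, cand_models
    # final likelihood with the last accepted state
    mix, _ = mixture(sll, w)
    ll = float(mix @ wpat)

    if base is not None and ll < base.log_likelihood - 1e-9:
        # degenerate but safe: all classes at the single-set optimum
        lengths = np.tile(lik.lengths_vector(base.lengths)[0], (H, 1))
        freqs = [model.frequencies.copy() for _ in range(H)]
        w = np.full(H, 1.0 / H)
        frozen = np.zeros(H, dtype=bool)
        ll = base.log_likelihood

    if frozen.any():
        warnings.warn(
            f"heterotachy classes {tuple(np.nonzero(frozen)[0])} collapsed "
            "(weight < collapse_tol) and were frozen", stacklevel=2,
        )

    order = np.argsort([lengths[h, : tree.root].sum() for h in range(H)])
    w = w / w.sum()
    class_lengths = [lik.lengths_dict(lengths[h]) for h in order]
    class_freqs = [freqs[h] for h in order]
    weights = w[order]
    combined_vec = (w[:, None] * lengths).sum(axis=0)
    frozen_sorted = tuple(
        int(np.nonzero(order == h)[0][0]) for h in np.nonzero(frozen)[0]
    )
    return HeterotachyFit(
        n_classes=H,
        weights=weights,
        class_lengths=class_lengths,
        class_frequencies=class_freqs,
        log_likelihood=ll,
        combined_lengths=lik.lengths_dict(combined_vec),
        frozen_classes=frozen_sorted,
        converged=converged,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# Site partitions
# ---------------------------------------------------------------------------


def categorize_sites(alignment: ResidueAlignment, n_categories: int = 8,
                     scheme: str = "equal_width") -> np.ndarray:
    """Assign each site a diversity category in ``1..n_categories``.

    The diversity score of a site is its count of distinct non-missing
    symbols.  ``equal_width`` (default) bins scores into equal-width bins
    over the achievable range [1, min(K, n_taxa)]; ``quantile`` bins by
    empirical quantiles of the observed scores.  Invariant sites land in
    category 1, maximally diverse sites in the top category; the result does
    not depend on taxon order.
    """
    if n_categories < 2:
        raise ValueError("n_categories must be >= 2")
    codes = alignment.codes()
    K = len(alignment.alphabet)
    div = np.array([
        max(len(np.unique(col[col >= 0])), 1) for col in codes.T
    ])
    lo, hi = 1, min(K, alignment.n_taxa)
    if hi <= lo:
        return np.ones(alignment.n_sites, dtype=int)
    if scheme == "equal_width":
        cat = 1 + np.floor(
            (div - lo) / (hi - lo) * n_categories
        ).astype(int)
        return np.clip(cat, 1, n_categories)
    if scheme == "quantile":
        qs = np.quantile(div, np.linspace(0, 1, n_categories + 1)[1:-1])
        return 1 + np.searchsorted(qs, div, side="left").astype(int)
    raise ValueError(f"unknown binning scheme {scheme!r}")


def effective_categories(site_categories: np.ndarray,
                         min_fraction: float = 0.05,
                         ) -> tuple[int, float]:
    """Count categories holding at least ``min_fraction`` of sites.

    Returns ``(count, cumulative_fraction)`` -- the number of effective
    categories and the total share of sites they contain.
    """
    cats = np.asarray(site_categories)
    if cats.size == 0:
        raise ValueError("empty site-category map")
    _, counts = np.unique(cats, return_counts=True)
    frac = counts / cats.size
    keep = frac >= min_fraction
    return int(keep.sum()), float(frac[keep].sum())


def fit_partitioned(alignment: ResidueAlignment, tree: LabeledTree,
                    model: RevModel, site_categories: np.ndarray, *,
                    min_sites: int = 5, pseudocount: float = 0.5,
                    tol: float = 1e-4) -> PartitionFit:
    """Edge-unlinked fit: independent branch lengths per site category.

    Every non-empty category gets its own empirical (+F) frequencies and its
    own branch-length optimisation under the shared exchangeabilities.
    Categories with fewer than ``min_sites`` sites are unestimable and are
    merged into the nearest non-small category (by category id; ties go
    down).  The combined per-branch length is the site-fraction-weighted
    mean over fitted categories and the total log-likelihood is the sum.
    """
    cats = np.asarray(site_categories).copy()
    if cats.size != alignment.n_sites:
        raise ValueError("site-category map length does not match alignment")
    present, counts = np.unique(cats, return_counts=True)
    big = [c for c, n in zip(present, counts) if n >= min_sites]
    merged: dict[int, int] = {}
    if big:
        for c, n in zip(present, counts):
            if n < min_sites:
                target = min(big, key=lambda b: (abs(b - c), b))
                merged[int(c)] = int(target)
                cats[cats == c] = target
    else:
        target = int(present[0])
        for c in present[1:]:
            merged[int(c)] = target
            cats[cats == c] = target
    if merged:
        warnings.warn(
            f"site categories {sorted(merged)} had fewer than {min_sites} "
            f"sites and were merged into neighbours {merged}", stacklevel=2,
        )

    groups = np.unique(cats)
    total_sites = cats.size
    cat_lengths: dict[int, dict[str, float]] = {}
    cat_freqs: dict[int, np.ndarray] = {}
    cat_ll: dict[int, float] = {}
    fractions: dict[int, float] = {}
    combined = None
    for c in groups:
        idx = np.nonzero(cats == c)[0]
        sub = alignment.select_columns(idx)
        freqs = empirical_frequencies(sub, pseudocount)
        sub_model = RevModel(
            model.exchangeabilities, freqs, model.alphabet
        )
        fit = optimize_branch_lengths(sub, tree, sub_model, tol=tol)
        frac = idx.size / total_sites
        cat_lengths[int(c)] = fit.lengths
        cat_freqs[int(c)] = freqs
        cat_ll[int(c)] = fit.log_likelihood
        fractions[int(c)] = frac
        vec = np.array([fit.lengths[lab] for lab in tree.branch_labels])
        combined = frac * vec if combined is None else combined + frac * vec
    combined_lengths = dict(zip(tree.branch_labels, map(float, combined)))
    return PartitionFit(
        site_categories=cats,
        category_lengths=cat_lengths,
        category_frequencies=cat_freqs,
        category_log_likelihoods=cat_ll,
        log_likelihood=float(sum(cat_ll.values())),
        site_fractions=fractions,
        combined_lengths=combined_lengths,
        merged=merged,
    )


def save_fit_json(fit, path) -> None:
    """Serialise a HeterotachyFit or PartitionFit report as JSON."""
    with open(path, "w") as fh:
        json.dump(fit.to_json_dict(), fh, indent=1)
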