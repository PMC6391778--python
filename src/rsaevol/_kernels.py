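"""Compiled inner loops for the likelihood engine.

The postorder pruning pass and the per-branch Newton sweep are small dense
array computations executed tens of thousands of times per analysis, so
they are compiled with numba when it is available; the numpy implementations
in :mod:`rsaevol.engine` remain the reference and are used as a fallback.
Both paths compute the same quantities in the same traversal order.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap

_RESCALE = 1e-240
_TINY = 1e-300


@njit(cache=True)
def down_pass(is_leaf, ch_off, ch_flat, leafD, lam, R, L, lengths, rescale):
    """Postorder conditional likelihoods for all classes.

    Returns ``D`` (n_nodes, H, n_pat, K) and per-pattern log scale factors
    ``S`` (n_nodes, H, n_pat).
    """
    n_nodes = is_leaf.size
    H, K = lam.shape
    n_pat = leafD.shape[1]
    D = np.empty((n_nodes, H, n_pat, K))
    S = np.zeros((n_nodes, H, n_pat))
    for v in range(n_nodes):
        if is_leaf[v]:
            for h in range(H):
                D[v, h] = leafD[v]
            continue
        first = True
        for ci in range(ch_off[v], ch_off[v + 1]):
            c = ch_flat[ci]
            for h in range(H):
                E = np.exp(lam[h] * lengths[h, c])
                P = np.dot(R[h] * E, L[h])
                M = np.dot(D[c, h], P.T)
                if first:
                    D[v, h, :, :] = M
                else:
                    D[v, h] *= M
                S[v, h] += S[c, h]
            first = False
        if rescale:
            for h in range(H):
                for p in range(n_pat):
                    m = D[v, h, p].max()
                    if 0.0 < m < _RESCALE:
                        D[v, h, p] /= m
                        S[v, h, p] += np.log(m)
    return D, S


@njit(cache=True)
def _edge_objective1(coef, lam1, ew1, t):
    K = lam1.size
    E = np.empty(K)
    for k in range(K):
        E[k] = np.exp(lam1[k] * t)
    f = np.dot(coef, E)
    q = 0.0
    for p in range(f.size):
        if f[p] < _TINY:
            f[p] = _TINY
        q += ew1[p] * np.log(f[p])
    return q, f, E


@njit(cache=True)
def edge_newton(coef, lam1, ew1, t0, lo, hi):
    """Safeguarded Newton maximisation of one class's edge objective."""
    t = t0
    if t < lo:
        t = lo
    elif t > hi:
        t = hi
    q, f, E = _edge_objective1(coef, lam1, ew1, t)
    for _ in range(8):
        f1 = np.dot(coef, lam1 * E)
        f2 = np.dot(coef, lam1 * lam1 * E)
        g = 0.0
        h = 0.0
        for p in range(f.size):
            r1 = f1[p] / f[p]
            g += ew1[p] * r1
            h += ew1[p] * (f2[p] / f[p] - r1 * r1)
        if h < -_TINY:
            step = -g / h
        elif g > 0:
            step = max(0.25 * t, 1e-4)
        elif g < 0:
            step = -max(0.25 * t, 1e-4)
        else:
            step = 0.0
        if step > 3.0:
            step = 3.0
        elif step < -3.0:
            step = -3.0
        tn = t + step
        if tn < lo:
            tn = lo
        elif tn > hi:
            tn = hi
        qn, fn, En = _edge_objective1(coef, lam1, ew1, tn)
        for _ in range(12):
            if qn >= q - 1e-12:
                break
            tn = 0.5 * (tn + t)
            qn, fn, En = _edge_objective1(coef, lam1, ew1, tn)
        if qn >= q - 1e-12:
            moved = abs(tn - t)
            t, q, f, E = tn, qn, fn, En
        else:
            moved = 0.0
        if moved < 1e-6 * (1.0 + t):
            break
    return t


@njit(cache=True)
def sweep_pass(is_leaf, ch_off, ch_flat, pi, lam, R, L, leafD,
               lengths, ew, lo, hi, rescale, D,
               process_edge, need_below):
    """One in-place branch-length sweep, all classes jointly.

    ``D`` is the postorder pass for the current lengths (from
    :func:`down_pass`); the preorder walk keeps the outside partials ``A``
    consistent with the lengths updated so far.  ``process_edge[c]`` selects
    the edges to optimise and ``need_below[c]`` marks subtrees that must be
    descended into (a full sweep passes all-True for both); partial sweeps
    still only ever increase the objective.  Returns the largest per-edge
    length move.
    """
    n_nodes = is_leaf.size
    H, K = lam.shape
    n_pat = leafD.shape[1]
    A = np.empty((n_nodes, H, n_pat, K))
    root = n_nodes - 1
    for h in range(H):
        for p in range(n_pat):
            A[root, h, p] = pi[h]
    active = np.empty(H, dtype=np.bool_)
    for h in range(H):
        active[h] = ew[h].sum() > 0.0
    moves = np.zeros(n_nodes)
    Ms = np.empty((8, H, n_pat, K))     # scratch for up to 8 children
    have_M = np.zeros(8, dtype=np.bool_)
    for v in range(n_nodes - 1, -1, -1):
        if is_leaf[v] or not need_below[v]:
            continue
        nk = ch_off[v + 1] - ch_off[v]
        relevant = np.zeros(nk, dtype=np.bool_)
        for j in range(nk):
            c = ch_flat[ch_off[v] + j]
            relevant[j] = process_edge[c] or need_below[c]
        for j in range(nk):
            have_M[j] = False
        for j in range(nk):
            c = ch_flat[ch_off[v] + j]
            if not relevant[j]:
                continue
            U = A[v].copy()
            for j2 in range(nk):
                if j2 == j:
                    continue
                if not have_M[j2]:
                    c2 = ch_flat[ch_off[v] + j2]
                    for h in range(H):
                        E = np.exp(lam[h] * lengths[h, c2])
                        P = np.dot(R[h] * E, L[h])
                        Ms[j2, h] = np.dot(D[c2, h], P.T)
                    have_M[j2] = True
                U *= Ms[j2]
            if process_edge[c]:
                for h in range(H):
                    if not active[h]:
                        continue
                    coef = np.dot(U[h], R[h]) * np.dot(D[c, h], L[h].T)
                    t_old = lengths[h, c]
                    t_new = edge_newton(
                        coef, lam[h], ew[h], t_old, lo, hi
                    )
                    lengths[h, c] = t_new
                    if abs(t_new - t_old) > moves[c]:
                        moves[c] = abs(t_new - t_old)
                have_M[j] = False   # stale after the update
            need_ms_later = False
            for j2 in range(j + 1, nk):
                if relevant[j2]:
                    need_ms_later = True
            need_A = need_below[c] and not is_leaf[c]
            if need_ms_later or need_A:
                for h in range(H):
                    E = np.exp(lam[h] * lengths[h, c])
                    P = np.dot(R[h] * E, L[h])
                    if need_ms_later:
                        Ms[j, h] = np.dot(D[c, h], P.T)
                    if need_A:
                        Ac = np.dot(U[h], P)
                        if rescale:
                            for p in range(n_pat):
                                m = Ac[p].max()
                                if 0.0 < m < _RESCALE:
                                    Ac[p] /= m
                        A[c, h] = Ac
                if need_ms_later:
                    have_M[j] = True
    return moves
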