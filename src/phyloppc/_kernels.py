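"""Compiled numerical kernels (numba) for the likelihood hot path.

These are internal: the public API lives in :mod:`phyloppc.likelihood`
and :mod:`phyloppc.mcmc`.  All kernels operate on the flat-array tree
representation of :class:`phyloppc.trees.PhyloTree`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "postorder_internal",
    "fill_jc_pmats",
    "fill_gtr_pmats",
    "pruning_loglik",
]


@njit(cache=True)
def postorder_internal(childmat, nchild, root, n_taxa, out):
    """Fill ``out`` with internal nodes in postorder (root last)."""
    n_int = out.size
    stack = np.empty(n_int, np.int32)
    seen = np.empty(n_int, np.int32)
    ns = 0
    nseen = 0
    stack[ns] = root
    ns += 1
    while ns > 0:
        ns -= 1
        v = stack[ns]
        seen[nseen] = v
        nseen += 1
        for i in range(nchild[v]):
            c = childmat[v, i]
            if c >= n_taxa:
                stack[ns] = c
                ns += 1
    for i in range(n_int):
        out[i] = seen[n_int - 1 - i]


@njit(cache=True)
def fill_jc_pmats(nodes, lengths, rates, pmats):
    """Jukes–Cantor transition matrices for the edges above ``nodes``,
    one per rate category: P_ii = 1/4 + 3/4 e^{-4d/3},
    P_ij = 1/4 - 1/4 e^{-4d/3} with d = rate * length."""
    for k in range(nodes.size):
        v = nodes[k]
        for cat in range(rates.size):
            d = rates[cat] * lengths[v]
            e = np.exp(-4.0 * d / 3.0)
            off = 0.25 - 0.25 * e
            diag = 0.25 + 0.75 * e
            for i in range(4):
                for j in range(4):
                    pmats[v, cat, i, j] = off
                pmats[v, cat, i, i] = diag


@njit(cache=True)
def fill_gtr_pmats(nodes, lengths, rates, left, w, right, pmats):
    """GTR transition matrices via the precomputed symmetric
    eigendecomposition: P(d) = left @ diag(exp(w d)) @ right."""
    ew = np.empty(4)
    for k in range(nodes.size):
        v = nodes[k]
        for cat in range(rates.size):
            d = rates[cat] * lengths[v]
            for i in range(4):
                ew[i] = np.exp(w[i] * d)
            for i in range(4):
                rowsum = 0.0
                for j in range(4):
                    s = 0.0
                    for m in range(4):
                        s += left[i, m] * ew[m] * right[m, j]
                    if s < 0.0:
                        s = 0.0
                    pmats[v, cat, i, j] = s
                    rowsum += s
                for j in range(4):
                    pmats[v, cat, i, j] /= rowsum


@njit(cache=True)
def pruning_loglik(post, childmat, nchild, n_taxa, pmats, tips, patw,
                   pi, catw, pinv, const_state, partials, logscale):
    """Felsenstein-pruning log-likelihood over compressed site patterns.

    ``partials`` is a workspace of shape (n_internal, n_cat, n_pat, 4);
    ``logscale`` of shape (n_pat,).  Per-pattern rescaling keeps the
    recursion in range for large trees.  ``catw`` are the mixture
    weights of the Gamma categories (already including the 1 - pinv
    factor); the invariable-site class contributes
    ``pinv * pi[state]`` for constant columns.
    """
    n_cat = pmats.shape[1]
    n_pat = tips.shape[1]
    for p in range(n_pat):
        logscale[p] = 0.0
    for idx in range(post.size):
        v = post[idx]
        pv = v - n_taxa
        nc = nchild[v]
        for cat in range(n_cat):
            for p in range(n_pat):
                for s in range(4):
                    val = 1.0
                    for ci in range(nc):
                        c = childmat[v, ci]
                        if c < n_taxa:
                            val *= pmats[c, cat, s, tips[c, p]]
                        else:
                            cc = c - n_taxa
                            acc = 0.0
                            for t in range(4):
                                acc += pmats[c, cat, s, t] * partials[cc, cat, p, t]
                            val *= acc
                    partials[pv, cat, p, s] = val
        # rescale per pattern across categories and states
        for p in range(n_pat):
            m = 0.0
            for cat in range(n_cat):
                for s in range(4):
                    if partials[pv, cat, p, s] > m:
                        m = partials[pv, cat, p, s]
            if 0.0 < m < 1e-40:
                inv = 1.0 / m
                for cat in range(n_cat):
                    for s in range(4):
                        partials[pv, cat, p, s] *= inv
                logscale[p] += np.log(m)
    rv = post[post.size - 1] - n_taxa
    total = 0.0
    for p in range(n_pat):
        lvar = 0.0
        for cat in range(n_cat):
            site = 0.0
            for s in range(4):
                site += pi[s] * partials[rv, cat, p, s]
            lvar += catw[cat] * site
        if lvar < 1e-300:
            lvar = 1e-300
        a = np.log(lvar) + logscale[p]
        if pinv > 0.0 and const_state[p] >= 0:
            b = np.log(pinv * pi[const_state[p]])
            if a > b:
                a = a + np.log1p(np.exp(b - a))
            else:
                a = b + np.log1p(np.exp(a - b))
        total += patw[p] * a
    return total
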