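"""Independent oracles used by the test suite.

Each function here recomputes a quantity by a route deliberately
different from the package implementation (brute-force enumeration,
quadrature, closed forms, or an independently coded formula), so the
tests compare two independent derivations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate
from scipy import stats as sps
from scipy.linalg import expm

from phyloppc.substitution import JC, rate_matrix, transition_matrix


def expm_transition(params, t, rate=1.0):
    """Transition matrix by scipy's scaling-and-squaring expm."""
    return expm(rate_matrix(params) * (rate * t))


def gamma_category_means(shape: float, k: int) -> np.ndarray:
    """Mean of each inter-quantile interval of Gamma(shape, rate=shape)
    by adaptive quadrature."""
    dist = sps.gamma(shape, scale=1.0 / shape)
    bounds = [dist.ppf(i / k) for i in range(k + 1)]
    out = np.empty(k)
    for i in range(k):
        hi = bounds[i + 1] if np.isfinite(bounds[i + 1]) else np.inf
        val, _ = integrate.quad(lambda x: x * dist.pdf(x), bounds[i], hi,
                                limit=200)
        out[i] = val * k  # divide by the interval probability 1/k
    return out


def enum_loglik(tree, params, aln) -> float:
    """Likelihood by brute-force summation over all internal-node state
    assignments (feasible for <= 6 taxa)."""
    n_taxa = tree.n_taxa
    internals = [v for v in range(tree.n_nodes) if v >= n_taxa]
    if params.model_flavor == JC:
        cats = [(1.0, 1.0)]
        pinv = 0.0
    else:
        rates = params.category_rates()
        pinv = params.pinv
        cats = [(r, (1.0 - pinv) / rates.size) for r in rates]
    pi = params.pi
    total = 0.0
    nonroot = [v for v in range(tree.n_nodes) if v != tree.root]
    for j in range(aln.n_sites):
        col = aln.codes[:, j]
        site = 0.0
        for rate, w in cats:
            pm = {v: transition_matrix(params, float(tree.lengths[v]),
                                       rate) if rate > 0 else np.eye(4)
                  for v in nonroot}
            acc = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                st = {v: assign[i] for i, v in enumerate(internals)}
                for leaf in range(n_taxa):
                    st[leaf] = int(col[leaf])
                prob = pi[st[tree.root]]
                for v in nonroot:
                    prob *= pm[v][st[int(tree.parent[v])], st[v]]
                acc += prob
            site += w * acc
        if pinv > 0 and (col == col[0]).all():
            site += pinv * pi[int(col[0])]
        total += math.log(site)
    return total


def three_taxon_pattern_probs(params, lengths) -> dict:
    """Analytic site-pattern probabilities for a 3-leaf star tree:
    P(x, y, z) = sum_s pi_s P_sx(b1) P_sy(b2) P_sz(b3)."""
    P = [transition_matrix(params, float(b)) for b in lengths]
    probs = {}
    for x, y, z in itertools.product(range(4), repeat=3):
        probs[(x, y, z)] = float(sum(
            params.pi[s] * P[0][s, x] * P[1][s, y] * P[2][s, z]
            for s in range(4)))
    return probs


def midpoint_pvalue_bruteforce(observed: float, predictive) -> float:
    """Direct count of the lower midpoint tail area."""
    below = ties = 0
    for v in predictive:
        if v == observed:
            ties += 1
        elif v < observed:
            below += 1
    return (below + 0.5 * ties) / len(predictive)


def tajimas_d_reference(n: int, s_seg: int, pi_hat: float) -> float:
    """Tajima's D from the published 1989 constants, coded separately
    from the package implementation."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = (2.0 * (n * n + n + 3.0)) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * s_seg + e2 * s_seg * (s_seg - 1.0)
    return (pi_hat - s_seg / a1) / math.sqrt(var)


def ordered_vector_quantile(values, q: float) -> float:
    """Element ceil(q * m) (1-indexed) of the sorted vector."""
    v = sorted(values)
    m = len(v)
    idx = min(m, max(1, math.ceil(q * m)))
    return float(v[idx - 1])


def dendropy_rf(t1, t2) -> int:
    """Robinson–Foulds distance via dendropy's bipartition machinery."""
    import dendropy
    from dendropy.calculate import treecompare

    tns = dendropy.TaxonNamespace()
    d1 = t1.to_dendropy(taxon_namespace=tns)
    d2 = t2.to_dendropy(taxon_namespace=tns)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return int(treecompare.symmetric_difference(d1, d2))
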