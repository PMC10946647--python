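"""Test statistics for posterior predictive checks.

Two families:

* **data-based** statistics are functions of an alignment alone
  (invariant-site counts and blocks, scaled pairwise differences, GC
  composition, Watterson's theta, Tajima's D and pi, the unconstrained
  multinomial log-likelihood of the site-pattern frequencies);
* **inference-based** statistics are functions of a posterior sample
  (Robinson–Foulds distance summaries between sampled trees, the
  information gain on the topology, and tree-length moments).

Conventions (fixed here and documented in the methods note):
"scaled" pairwise differences are mismatch proportions; Watterson's
theta and Tajima's pi are per-alignment counts, not per-site rates
(P-values are invariant to any monotone rescaling shared by the
observed and predictive values); RF quantiles use the ordered-vector
convention (element ``ceil(q * m)`` of the sorted length-``m`` vector);
the topology information gain is the prior Shannon entropy of the
uniform topology distribution minus the empirical posterior entropy,
in nats.
"""

from __future__ import annotations

import math

import numpy as np

from phyloppc.mcmc import PosteriorTrace
from phyloppc.simulate import Alignment
from phyloppc.trees import PhyloTree

__all__ = [
    "DATA_STATISTICS", "INFERENCE_STATISTICS",
    "compute_data_statistics", "compute_inference_statistics",
    "invariant_site_stats", "pairwise_difference_stats", "gc_stats",
    "watterson_theta", "tajimas_pi", "tajimas_d", "multinomial_likelihood",
    "rf_distance", "rf_summary", "topology_entropy", "tree_length_stats",
]

#: seed of the deterministic pair subsample used by ``rf_summary`` when
#: the trace holds more than ``_RF_ALL_PAIRS_MAX`` trees
_RF_PAIR_SEED = 20_240_304
_RF_ALL_PAIRS_MAX = 200
_RF_N_RANDOM_PAIRS = 20_000


def _max_run(mask: np.ndarray) -> int:
    """Length of the longest run of True; 0 for an all-False mask."""
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        if cur > best:
            best = cur
    return best


def invariant_site_stats(aln: Alignment):
    """(number of invariant columns, longest invariant block, longest
    variable block).  A column is invariant iff all characters agree."""
    inv = (aln.codes == aln.codes[0]).all(axis=0)
    return int(inv.sum()), _max_run(inv), _max_run(~inv)


def _pairwise_mismatches(aln: Alignment) -> np.ndarray:
    """Condensed vector of pairwise mismatch counts."""
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 sequences")
    n = aln.n_taxa
    out = []
    for i in range(n - 1):
        out.append((aln.codes[i + 1:] != aln.codes[i]).sum(axis=1))
    return np.concatenate(out)


def pairwise_difference_stats(aln: Alignment):
    """(min, max) over sequence pairs of the mismatch proportion."""
    mm = _pairwise_mismatches(aln) / aln.n_sites
    return float(mm.min()), float(mm.max())


def gc_stats(aln: Alignment):
    """(mean, variance) across sequences of the per-sequence GC
    fraction; variance with denominator n - 1."""
    gc = ((aln.codes == 1) | (aln.codes == 2)).mean(axis=1)
    return float(gc.mean()), float(gc.var(ddof=1))


def _harmonic(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def watterson_theta(aln: Alignment) -> float:
    """Watterson's theta: segregating-site count divided by the
    harmonic number a1 = sum_{i<n} 1/i (per alignment, not per site)."""
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 sequences")
    s_seg = aln.n_sites - invariant_site_stats(aln)[0]
    return s_seg / _harmonic(aln.n_taxa)


def tajimas_pi(aln: Alignment) -> float:
    """Mean pairwise mismatch count over unordered sequence pairs."""
    return float(_pairwise_mismatches(aln).mean())


def tajimas_d(aln: Alignment) -> float:
    """Tajima's D with the standard 1989 constants.

    Undefined (NaN) when there are no segregating sites; callers count
    and exclude such replicates rather than imputing a value.
    """
    n = aln.n_taxa
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 sequences")
    s_seg = aln.n_sites - invariant_site_stats(aln)[0]
    if s_seg == 0:
        return float("nan")
    pi_hat = tajimas_pi(aln)
    a1 = _harmonic(n)
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    denom = math.sqrt(e1 * s_seg + e2 * s_seg * (s_seg - 1))
    return (pi_hat - s_seg / a1) / denom


def multinomial_likelihood(aln: Alignment) -> float:
    """Unconstrained multinomial log-likelihood of the site-pattern
    frequencies: sum_p N_p ln(N_p / N)."""
    _, counts = np.unique(aln.codes, axis=1, return_counts=True)
    N = aln.n_sites
    return float(np.sum(counts * (np.log(counts) - math.log(N))))


# ----------------------------------------------------------------------
# inference-based statistics
# ----------------------------------------------------------------------
def _canonical_splits(tree: PhyloTree, bit_of: dict) -> frozenset:
    """Nontrivial splits as bitmasks under a shared label->bit map."""
    n = len(bit_of)
    full = (1 << n) - 1
    first_bit = 1  # bit 0 defines the reference side
    masks = {}
    splits = []
    for v in range(tree.n_taxa):
        masks[v] = 1 << bit_of[tree.taxa[v]]
    for v in tree.postorder_internal():
        m = 0
        for i in range(tree.nchild[v]):
            m |= masks[tree.childmat[v, i]]
        masks[v] = m
        if v != tree.root:
            if m & first_bit:
                m = full & ~m
            bc = bin(m).count("1")
            if 2 <= bc <= n - 2:
                splits.append(m)
    return frozenset(splits)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Unnormalised Robinson–Foulds distance: size of the symmetric
    difference of the nontrivial bipartition sets."""
    if set(t1.taxa) != set(t2.taxa):
        raise ValueError("trees have different leaf sets")
    bit_of = {lab: i for i, lab in enumerate(sorted(t1.taxa))}
    s1 = _canonical_splits(t1, bit_of)
    s2 = _canonical_splits(t2, bit_of)
    return len(s1 ^ s2)


def _trace_splits(trace: PosteriorTrace):
    bit_of = {lab: i for i, lab in enumerate(sorted(trace.taxa))}
    return [_canonical_splits(t, bit_of) for t in trace.trees]


def rf_summary(trace: PosteriorTrace):
    """(mean, q25, q50, q75, q99, q999) of RF distances between sampled
    trees.

    All unordered pairs are used for up to 200 trees; larger traces use
    a fixed-seed subsample of 20,000 random pairs.  Quantiles follow the
    ordered-vector convention: element ``ceil(q * m)`` (1-indexed) of
    the sorted length-``m`` distance vector.
    """
    m = len(trace)
    if m < 2:
        raise ValueError("need at least 2 sampled trees")
    splits = _trace_splits(trace)
    if m <= _RF_ALL_PAIRS_MAX:
        dists = [len(splits[i] ^ splits[j])
                 for i in range(m) for j in range(i + 1, m)]
    else:
        rng = np.random.default_rng(_RF_PAIR_SEED)
        ii = rng.integers(0, m, size=_RF_N_RANDOM_PAIRS)
        jj = rng.integers(0, m - 1, size=_RF_N_RANDOM_PAIRS)
        jj = np.where(jj >= ii, jj + 1, jj)  # exclude self-pairs
        dists = [len(splits[i] ^ splits[j]) for i, j in zip(ii, jj)]
    v = np.sort(np.asarray(dists, dtype=float))
    k = v.size

    def quant(q):
        return float(v[min(k, max(1, math.ceil(q * k))) - 1])

    return (float(v.mean()), quant(0.25), quant(0.50), quant(0.75),
            quant(0.99), quant(0.999))


def topology_entropy(trace: PosteriorTrace, n_taxa: int | None = None) -> float:
    """Information gain on the topology: ln((2n-5)!!) minus the Shannon
    entropy of the empirical topology frequencies (natural log).

    When every sampled topology is unique the posterior entropy is
    ``ln m``, so the statistic is the same constant across traces of
    equal size — the diffuse-posterior regime.
    """
    if len(trace) < 1:
        raise ValueError("need at least 1 sampled tree")
    if n_taxa is None:
        n_taxa = trace.n_taxa
    log_prior_states = sum(math.log(k) for k in range(3, 2 * n_taxa - 4, 2))
    counts: dict = {}
    for t in trace.trees:
        key = t.topology_key()
        counts[key] = counts.get(key, 0) + 1
    m = len(trace)
    post_entropy = -sum((c / m) * math.log(c / m) for c in counts.values())
    return log_prior_states - post_entropy


def tree_length_stats(trace: PosteriorTrace):
    """(mean, variance) of the summed branch lengths across samples;
    variance with denominator n - 1."""
    if len(trace) < 2:
        raise ValueError("need at least 2 samples for the variance")
    tl = trace.tree_lengths()
    return float(tl.mean()), float(tl.var(ddof=1))


# ----------------------------------------------------------------------
# registry
# ----------------------------------------------------------------------
DATA_STATISTICS = {
    "n_invariant_sites": lambda a: float(invariant_site_stats(a)[0]),
    "max_invariant_block": lambda a: float(invariant_site_stats(a)[1]),
    "max_variable_block": lambda a: float(invariant_site_stats(a)[2]),
    "min_pairwise_diff": lambda a: pairwise_difference_stats(a)[0],
    "max_pairwise_diff": lambda a: pairwise_difference_stats(a)[1],
    "mean_gc": lambda a: gc_stats(a)[0],
    "var_gc": lambda a: gc_stats(a)[1],
    "watterson_theta": watterson_theta,
    "tajimas_d": tajimas_d,
    "tajimas_pi": tajimas_pi,
    "multinomial_likelihood": multinomial_likelihood,
}

INFERENCE_STATISTICS = {
    "mean_rf": lambda tr: rf_summary(tr)[0],
    "rf_q25": lambda tr: rf_summary(tr)[1],
    "rf_q50": lambda tr: rf_summary(tr)[2],
    "rf_q75": lambda tr: rf_summary(tr)[3],
    "rf_q99": lambda tr: rf_summary(tr)[4],
    "rf_q999": lambda tr: rf_summary(tr)[5],
    "topology_entropy": topology_entropy,
    "mean_tl": lambda tr: tree_length_stats(tr)[0],
    "var_tl": lambda tr: tree_length_stats(tr)[1],
}

#: statistics whose value may be undefined (NaN) on some datasets
UNDEFINED_CAPABLE = {"tajimas_d"}


def compute_data_statistics(aln: Alignment) -> dict:
    """All 11 data-based statistics in one pass (shared intermediates
    computed once)."""
    n_inv, max_inv, max_var = invariant_site_stats(aln)
    mm = _pairwise_mismatches(aln)
    gc_mean, gc_var = gc_stats(aln)
    s_seg = aln.n_sites - n_inv
    out = {
        "n_invariant_sites": float(n_inv),
        "max_invariant_block": float(max_inv),
        "max_variable_block": float(max_var),
        "min_pairwise_diff": float(mm.min()) / aln.n_sites,
        "max_pairwise_diff": float(mm.max()) / aln.n_sites,
        "mean_gc": gc_mean,
        "var_gc": gc_var,
        "watterson_theta": s_seg / _harmonic(aln.n_taxa),
        "tajimas_d": tajimas_d(aln),
        "tajimas_pi": float(mm.mean()),
        "multinomial_likelihood": multinomial_likelihood(aln),
    }
    return out


def compute_inference_statistics(trace: PosteriorTrace) -> dict:
    """All 9 inference-based statistics of one posterior trace."""
    mean_rf, q25, q50, q75, q99, q999 = rf_summary(trace)
    mean_tl, var_tl = tree_length_stats(trace)
    return {
        "mean_rf": mean_rf, "rf_q25": q25, "rf_q50": q50, "rf_q75": q75,
        "rf_q99": q99, "rf_q999": q999,
        "topology_entropy": topology_entropy(trace),
        "mean_tl": mean_tl, "var_tl": var_tl,
    }
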