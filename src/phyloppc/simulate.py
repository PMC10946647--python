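"""Sequence alignments and simulation along a tree.

Sites evolve independently.  Per site a rate class is drawn (rate 0
with probability ``pinv``, else one of the discrete-Gamma categories,
all equally likely), the state at the virtual root is drawn from the
stationary frequencies, and states are propagated to the leaves through
the transition probabilities of each edge.  All models here are
time-reversible, so the placement of the virtual root does not affect
the distribution of the simulated data (pulley principle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from phyloppc.substitution import JC, ModelParams, transition_matrix
from phyloppc.trees import PhyloTree

__all__ = ["Alignment", "simulate_alignment"]

#: nucleotide code order used throughout: A=0, C=1, G=2, T=3
CODES = "ACGT"
_CODE_OF = {b: i for i, b in enumerate(CODES)}


@dataclass
class Alignment:
    """DNA character matrix: ``codes[i, j]`` is the nucleotide code
    (A=0, C=1, G=2, T=3) of taxon ``taxa[i]`` at site ``j``.

    Simulated data only: strictly ACGT, no gaps or ambiguity codes.
    """

    taxa: list
    codes: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.codes = np.ascontiguousarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise ValueError("codes must be (n_taxa, n_sites)")
        if self.codes.size and self.codes.max() > 3:
            raise ValueError("nucleotide codes must be in 0..3 (ACGT)")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon labels must be unique")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def sequence(self, i: int) -> str:
        return "".join(CODES[c] for c in self.codes[i])

    @classmethod
    def from_sequences(cls, taxa, seqs) -> "Alignment":
        seqs = [str(s).upper() for s in seqs]
        if len({len(s) for s in seqs}) > 1:
            raise ValueError("sequences must have equal length")
        codes = np.empty((len(seqs), len(seqs[0]) if seqs else 0), np.uint8)
        for i, s in enumerate(seqs):
            for j, b in enumerate(s):
                if b not in _CODE_OF:
                    raise ValueError(
                        f"invalid character {b!r} in sequence {taxa[i]!r} "
                        f"at position {j + 1}")
                codes[i, j] = _CODE_OF[b]
        return cls(list(taxa), codes)

    def __eq__(self, other):
        return (isinstance(other, Alignment) and self.taxa == other.taxa
                and self.codes.shape == other.codes.shape
                and bool((self.codes == other.codes).all()))


def _preorder_nonroot(tree: PhyloTree):
    order = []
    stack = [tree.root]
    while stack:
        v = stack.pop()
        if v != tree.root:
            order.append(v)
        for i in range(tree.nchild[v]):
            stack.append(int(tree.childmat[v, i]))
    return order


def simulate_alignment(tree: PhyloTree, params: ModelParams, n_sites: int,
                       rng: np.random.Generator) -> Alignment:
    """Simulate an alignment of ``n_sites`` i.i.d. sites on ``tree``."""
    if n_sites < 1:
        raise ValueError(f"n_sites must be positive, got {n_sites}")
    lens = np.delete(tree.lengths, tree.root)
    if np.isnan(lens).any():
        raise ValueError("tree has unset branch lengths")
    n_nodes = tree.n_nodes

    # per-site rates: invariable class, then equally likely Gamma categories
    rates = np.ones(n_sites)
    if params.model_flavor != JC:
        cat_rates = params.category_rates()
        u = rng.random(n_sites)
        cats = rng.integers(0, cat_rates.size, size=n_sites)
        rates = np.where(u < params.pinv, 0.0, cat_rates[cats])

    states = np.empty((n_nodes, n_sites), dtype=np.uint8)
    # root states from the stationary distribution (all sites at once)
    states[tree.root] = rng.choice(4, size=n_sites, p=params.pi)

    pre = _preorder_nonroot(tree)
    for rate in np.unique(rates):
        cols = np.flatnonzero(rates == rate)
        if rate == 0.0:  # invariable class: copy the root state down
            for v in pre:
                states[v, cols] = states[tree.root, cols]
            continue
        for v in pre:
            P = transition_matrix(params, float(tree.lengths[v]), float(rate))
            cum = P.cumsum(axis=1)
            cum[:, 3] = 1.0
            u = rng.random(cols.size)
            parent_states = states[tree.parent[v], cols]
            states[v, cols] = (u[:, None] > cum[parent_states]).sum(axis=1)
    return Alignment(list(tree.taxa), states[: tree.n_taxa])
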