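"""Felsenstein-pruning likelihood with site-pattern compression."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from phyloppc import _kernels
from phyloppc.simulate import Alignment
from phyloppc.substitution import JC, ModelParams, eigensystem
from phyloppc.trees import PhyloTree

__all__ = ["PatternTable", "compress_patterns", "log_likelihood",
           "LikelihoodEngine"]


@dataclass
class PatternTable:
    """Distinct alignment columns with multiplicities.

    ``patterns`` has shape (n_taxa, n_patterns) with rows ordered as
    ``taxa``; ``weights`` are the column counts and sum to ``n_sites``.
    ``const_state`` holds, per pattern, the shared nucleotide code of a
    constant column, or -1 for variable columns (used by the
    invariable-sites mixture class).
    """

    taxa: list
    patterns: np.ndarray
    weights: np.ndarray
    n_sites: int
    const_state: np.ndarray

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]


def compress_patterns(aln: Alignment) -> PatternTable:
    """Collapse identical alignment columns into weighted patterns.

    The pruning likelihood evaluated on the compressed table equals the
    likelihood of the raw alignment (site independence)."""
    patterns, counts = np.unique(aln.codes, axis=1, return_counts=True)
    const = np.where((patterns == patterns[0]).all(axis=0),
                     patterns[0].astype(np.int8), np.int8(-1))
    return PatternTable(
        taxa=list(aln.taxa),
        patterns=np.ascontiguousarray(patterns, dtype=np.uint8),
        weights=counts.astype(np.float64),
        n_sites=aln.n_sites,
        const_state=const,
    )


class LikelihoodEngine:
    """Reusable pruning-likelihood evaluator for one pattern table.

    Holds the preallocated partial-likelihood workspace and the
    transition matrices keyed to the node-attached branch lengths, so
    the MCMC sampler can update single edges cheaply.
    """

    def __init__(self, pt: PatternTable, taxa_order: list):
        if set(pt.taxa) != set(taxa_order):
            raise ValueError(
                "tree taxa do not match alignment taxa: "
                f"tree-only={sorted(set(taxa_order) - set(pt.taxa))}, "
                f"alignment-only={sorted(set(pt.taxa) - set(taxa_order))}")
        n_taxa = len(taxa_order)
        row = {lab: i for i, lab in enumerate(pt.taxa)}
        order = np.array([row[lab] for lab in taxa_order])
        self.tips = np.ascontiguousarray(pt.patterns[order])
        self.patw = pt.weights
        self.const_state = pt.const_state
        self.n_taxa = n_taxa
        self.n_nodes = 2 * n_taxa - 2
        self._partials = None
        self._logscale = np.empty(pt.n_patterns)
        self._pmats = None
        self._eig = None

    def _ensure(self, n_cat: int):
        if self._pmats is None or self._pmats.shape[1] != n_cat:
            self._pmats = np.empty((self.n_nodes, n_cat, 4, 4))
            self._partials = np.empty(
                (self.n_nodes - self.n_taxa, n_cat, self.tips.shape[1], 4))
        return self._pmats

    def mixture(self, params: ModelParams):
        """Category rates and weights of the rate mixture."""
        rates = params.category_rates()
        if params.model_flavor == JC:
            catw = np.ones(1)
        else:
            catw = np.full(rates.size, (1.0 - params.pinv) / rates.size)
        return rates, catw

    def fill_pmats(self, tree: PhyloTree, params: ModelParams,
                   rates: np.ndarray, nodes=None):
        """(Re)compute transition matrices for the given edges
        (default: all)."""
        pmats = self._ensure(rates.size)
        if nodes is None:
            nodes = tree.edge_nodes()
        if params.model_flavor == JC:
            _kernels.fill_jc_pmats(nodes, tree.lengths, rates, pmats)
        else:
            if self._eig is None:
                self._eig = eigensystem(params)
            left, w, right = self._eig
            _kernels.fill_gtr_pmats(nodes, tree.lengths, rates, left, w,
                                    right, pmats)
        return pmats

    def invalidate_eigen(self):
        self._eig = None

    def loglik(self, tree: PhyloTree, params: ModelParams,
               postorder=None) -> float:
        """Pruning log-likelihood assuming ``fill_pmats`` is current."""
        if postorder is None:
            postorder = tree.postorder_internal()
        rates, catw = self.mixture(params)
        pmats = self._ensure(rates.size)
        return _kernels.pruning_loglik(
            postorder, tree.childmat, tree.nchild, self.n_taxa, pmats,
            self.tips, self.patw, params.pi, catw, params.pinv,
            self.const_state, self._partials, self._logscale)

    def full_loglik(self, tree: PhyloTree, params: ModelParams) -> float:
        """Recompute everything (transition matrices and pruning)."""
        self.invalidate_eigen()
        rates, _ = self.mixture(params)
        self.fill_pmats(tree, params, rates)
        return self.loglik(tree, params)


def log_likelihood(tree: PhyloTree, params: ModelParams,
                   pt: PatternTable) -> float:
    """Log-likelihood of the compressed alignment under ``tree`` and
    ``params``.

    The mixture over rate classes is summed per site: the invariable
    class contributes only to constant columns (weighted by ``pinv`` and
    the frequency of the shared state), the discrete-Gamma categories
    carry the remaining ``1 - pinv`` mass.
    """
    engine = LikelihoodEngine(pt, tree.taxa)
    return engine.full_loglik(tree, params)
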