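"""Predictive-dataset generation.

Three sources of parameter draws feed the same simulation kernel:

* ``posterior`` — draws from an MCMC trace (posterior predictive
  check);
* ``prior`` — i.i.d. draws from the priors (prior predictive check,
  the Bayesian analogue of a fixed-null frequentist test);
* ``fixed`` — a single supplied (tree, parameters) state (the
  fixed-parameter null of a classical hypothesis test).

Every predictive alignment has the same dimensions as the observed
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from phyloppc.mcmc import PosteriorTrace
from phyloppc.simulate import simulate_alignment
from phyloppc.substitution import ModelParams, PriorSpec, draw_model_params
from phyloppc.trees import PhyloTree, sample_branch_lengths, sample_topology

__all__ = ["PredictiveSet", "posterior_predictive", "prior_predictive",
           "fixed_predictive", "DEFAULT_S_DATA", "DEFAULT_S_INFERENCE"]

#: default predictive-sample sizes: 1,001 datasets for data-based test
#: statistics, 501 for the (far costlier) inference-based ones
DEFAULT_S_DATA = 1001
DEFAULT_S_INFERENCE = 501


@dataclass
class PredictiveSet:
    """S predictive alignments plus the parameter draws behind them."""

    source: str  # posterior | prior | fixed
    datasets: list
    thetas: list  # (PhyloTree, ModelParams) per dataset

    def __len__(self):
        return len(self.datasets)

    def __post_init__(self):
        if len(self.datasets) != len(self.thetas):
            raise ValueError("datasets and thetas must align")


def _even_indices(n_available: int, S: int) -> np.ndarray:
    """S indices evenly spaced over the trace, wrapping when S exceeds
    the number of available draws."""
    return (np.floor(np.arange(S) * n_available / S).astype(int)
            % n_available) if S else np.array([], dtype=int)


def posterior_predictive(trace: PosteriorTrace, n_sites: int, S: int,
                         rng: np.random.Generator,
                         mode: str = "even") -> PredictiveSet:
    """Simulate ``S`` datasets from parameter draws of a posterior
    trace.

    ``mode="even"`` (default) takes evenly spaced thinned indices —
    lower variance than resampling; ``mode="iid"`` resamples draws with
    replacement for sensitivity checks.
    """
    if len(trace) == 0:
        raise ValueError("posterior trace is empty")
    if mode == "even":
        idx = _even_indices(len(trace), S)
    elif mode == "iid":
        idx = rng.integers(0, len(trace), size=S)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    thetas = [(trace.trees[i], trace.params[i]) for i in idx]
    datasets = [simulate_alignment(t, p, n_sites, rng) for t, p in thetas]
    return PredictiveSet("posterior", datasets, thetas)


def prior_predictive(spec: PriorSpec, n_sites: int, S: int,
                     rng: np.random.Generator) -> PredictiveSet:
    """Simulate ``S`` datasets from i.i.d. prior draws."""
    thetas = []
    datasets = []
    for _ in range(S):
        tree = sample_branch_lengths(sample_topology(spec.n_taxa, rng),
                                     spec.bl_rate, rng)
        params = draw_model_params(spec, rng)
        thetas.append((tree, params))
        datasets.append(simulate_alignment(tree, params, n_sites, rng))
    return PredictiveSet("prior", datasets, thetas)


def fixed_predictive(theta, n_sites: int, S: int,
                     rng: np.random.Generator) -> PredictiveSet:
    """Simulate ``S`` datasets under one fixed (tree, parameters)."""
    tree, params = theta
    datasets = [simulate_alignment(tree, params, n_sites, rng)
                for _ in range(S)]
    return PredictiveSet("fixed", datasets, [(tree, params)] * S)
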