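"""Substitution models, priors and transition probabilities.

Two model flavours are supported: Jukes–Cantor (``JC``, equal base
frequencies and exchangeabilities, a single rate category) and the
general time-reversible model with discrete-Gamma rate variation and a
proportion of invariable sites (``GTR_GI``).

Conventions fixed throughout the package:

* nucleotide order ``A, C, G, T``;
* exchangeability order ``AC, AG, AT, CG, CT, GT``;
* the rate matrix is normalised so that the mean substitution rate at
  stationarity is 1 over the discrete-Gamma mixture; the invariable
  class is excluded from the normalisation, so branch lengths are in
  expected substitutions per variable-process site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc, gammaincinv

NUCLEOTIDES = "ACGT"
EXCH_PAIRS = ("AC", "AG", "AT", "CG", "CT", "GT")

#: (i, j) index pairs for the exchangeability order AC,AG,AT,CG,CT,GT.
_PAIR_INDEX = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

JC = "JC"
GTR_GI = "GTR_GI"


@dataclass(frozen=True)
class PriorSpec:
    """Prior specification for one simulation/analysis condition.

    Parameters
    ----------
    n_taxa
        Number of leaves; the topology prior is uniform over unrooted
        labelled binary trees on these taxa.
    bl_rate
        Rate of the i.i.d. Exponential prior on branch lengths
        (mean branch length ``1 / bl_rate``).
    model_flavor
        ``"JC"`` or ``"GTR_GI"``.
    pi_alpha
        Dirichlet concentration for the equilibrium base frequencies.
    er_alpha
        Dirichlet concentration for the exchangeabilities.
    shape_rate
        Rate of the Exponential prior on the Gamma shape parameter.
    pinv_beta
        ``(alpha, beta)`` of the Beta prior on the proportion of
        invariable sites.
    """

    n_taxa: int
    bl_rate: float = 10.0
    model_flavor: str = JC
    pi_alpha: tuple = (1.0, 1.0, 1.0, 1.0)
    er_alpha: tuple = (1.0,) * 6
    shape_rate: float = 0.05
    pinv_beta: tuple = (10.0, 20.0)

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError(f"need at least 4 taxa, got {self.n_taxa}")
        if self.bl_rate <= 0 or self.shape_rate <= 0:
            raise ValueError("rates must be strictly positive")
        if self.model_flavor not in (JC, GTR_GI):
            raise ValueError(f"unknown model flavor {self.model_flavor!r}")
        if len(self.pi_alpha) != 4 or len(self.er_alpha) != 6:
            raise ValueError("pi_alpha must have 4 entries, er_alpha 6")
        if any(a <= 0 for a in self.pi_alpha) or any(a <= 0 for a in self.er_alpha):
            raise ValueError("Dirichlet concentrations must be positive")
        if len(self.pinv_beta) != 2 or any(a <= 0 for a in self.pinv_beta):
            raise ValueError("pinv_beta must be two positive reals")


@dataclass
class ModelParams:
    """Concrete substitution-model parameters.

    ``pi`` and ``er`` live on the 4- and 6-simplex; ``shape`` is the
    Gamma shape parameter alpha; ``pinv`` the proportion of invariable
    sites in [0, 1).  ``n_categories`` is the number of discrete Gamma
    categories (1 for JC, 4 for GTR+Gamma+I).
    """

    pi: np.ndarray
    er: np.ndarray
    shape: float
    pinv: float
    n_categories: int = 4
    model_flavor: str = GTR_GI

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.er = np.asarray(self.er, dtype=float)
        if abs(self.pi.sum() - 1.0) > 1e-12 or abs(self.er.sum() - 1.0) > 1e-12:
            raise ValueError("pi and er must each sum to 1")
        if not (0.0 <= self.pinv <= 1.0):
            raise ValueError("pinv must lie in [0, 1]")
        if self.shape <= 0:
            raise ValueError("Gamma shape must be positive")

    def category_rates(self) -> np.ndarray:
        """Discrete-Gamma category rates (all 1 for JC)."""
        if self.model_flavor == JC:
            return np.ones(1)
        return discretize_gamma(self.shape, self.n_categories)

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.pi.copy(), self.er.copy(), self.shape, self.pinv,
            self.n_categories, self.model_flavor,
        )


def jc_params() -> ModelParams:
    """The fixed Jukes–Cantor parameters: equal frequencies, equal
    exchangeabilities, no rate variation, no invariable class."""
    return ModelParams(
        pi=np.full(4, 0.25),
        er=np.full(6, 1.0 / 6.0),
        shape=1.0,
        pinv=0.0,
        n_categories=1,
        model_flavor=JC,
    )


def draw_model_params(spec: PriorSpec, rng: np.random.Generator) -> ModelParams:
    """Draw substitution parameters from the prior.

    JC has no free substitution parameters, so its fixed values are
    returned.  For GTR+Gamma+I: ``pi ~ Dirichlet(pi_alpha)``,
    ``er ~ Dirichlet(er_alpha)``, ``shape ~ Exponential(shape_rate)``,
    ``pinv ~ Beta(*pinv_beta)``.
    """
    if spec.model_flavor == JC:
        return jc_params()
    return ModelParams(
        pi=rng.dirichlet(spec.pi_alpha),
        er=rng.dirichlet(spec.er_alpha),
        shape=rng.exponential(1.0 / spec.shape_rate),
        pinv=rng.beta(*spec.pinv_beta),
        n_categories=4,
        model_flavor=GTR_GI,
    )


def discretize_gamma(shape: float, k: int) -> np.ndarray:
    """Discretise a mean-1 Gamma(shape, rate=shape) into ``k`` equal
    probability categories, each represented by the mean of its
    inter-quantile interval.

    The mean-of-interval construction keeps the average rate exactly 1
    regardless of the shape parameter.
    """
    if shape <= 0:
        raise ValueError(f"Gamma shape must be positive, got {shape}")
    if k < 1:
        raise ValueError(f"need at least one category, got {k}")
    if k == 1:
        return np.ones(1)
    # Quantile boundaries of the standard Gamma(shape) distribution;
    # for X ~ Gamma(a, rate=a): E[X | z_i < a X < z_{i+1}] * (1/k)
    #   = (1/a) * a * [P(a+1, z_{i+1}) - P(a+1, z_i)]
    # with P the regularised lower incomplete gamma function.
    z = gammaincinv(shape, np.arange(1, k) / k)
    upper = np.concatenate([gammainc(shape + 1.0, z), [1.0]])
    lower = np.concatenate([[0.0], gammainc(shape + 1.0, z)])
    rates = k * (upper - lower)
    return rates / rates.mean()  # remove residual floating-point drift


def rate_matrix(params: ModelParams) -> np.ndarray:
    """Normalised GTR rate matrix Q with ``Q_ij = er_ij * pi_j`` for
    ``i != j``, scaled so the mean rate at stationarity is 1
    (``-sum_i pi_i Q_ii = 1``)."""
    pi, er = params.pi, params.er
    Q = np.zeros((4, 4))
    for r, (i, j) in zip(er, _PAIR_INDEX):
        Q[i, j] = r * pi[j]
        Q[j, i] = r * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    if mu <= 0:
        raise ValueError("degenerate rate matrix (zero mean rate)")
    return Q / mu


def eigensystem(params: ModelParams):
    """Symmetric eigendecomposition of the normalised rate matrix.

    Returns ``(left, w, right)`` with
    ``P(t) = left @ diag(exp(w * t)) @ right``.  The similarity
    transform ``B = D^{1/2} Q D^{-1/2}`` (D = diag(pi)) is symmetric for
    any time-reversible Q, so `numpy.linalg.eigh` applies.
    """
    Q = rate_matrix(params)
    sq = np.sqrt(params.pi)
    B = (Q * sq[:, None]) / sq[None, :]
    B = 0.5 * (B + B.T)  # symmetrise away rounding noise
    w, V = np.linalg.eigh(B)
    left = V / sq[:, None]
    right = V.T * sq[None, :]
    return left, w, right


def transition_matrix(params: ModelParams, t: float, rate: float = 1.0) -> np.ndarray:
    """Transition probability matrix ``P(rate * t)``.

    ``t`` is the branch length in expected substitutions per site (before
    the per-site rate multiplier).  JC uses the closed form; GTR the
    eigendecomposition route.
    """
    if t < 0:
        raise ValueError(f"branch length must be nonnegative, got {t}")
    if rate <= 0:
        raise ValueError(f"rate multiplier must be positive, got {rate}")
    d = rate * t
    if params.model_flavor == JC:
        e = np.exp(-4.0 * d / 3.0)
        P = np.full((4, 4), 0.25 - 0.25 * e)
        np.fill_diagonal(P, 0.25 + 0.75 * e)
        return P
    left, w, right = eigensystem(params)
    P = (left * np.exp(w * d)) @ right
    np.clip(P, 0.0, None, out=P)
    return P / P.sum(axis=1, keepdims=True)
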