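"""Midpoint P-values, posterior predictive effect sizes, and
distribution summaries across replicate datasets.

The reported P-value is the lower one-tailed *midpoint* P-value

    p = (#{T_rep < T_obs} + 0.5 * #{T_rep = T_obs}) / S ,

which counts half of the predictive values tied with the observed value
as more extreme — the natural choice for discrete statistics, where
ties are common.  The effect size is

    PPES = |T_obs - median(T_rep)| / sd(T_rep) ,

the distance from the predictive median in predictive standard
deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["PPSummary", "DistributionSummary", "midpoint_pvalue",
           "effect_size", "summarize_stat", "aggregate",
           "statistic_correlations"]

#: relative tolerance for tie detection on continuous statistics;
#: independent simulations tie only through floating-point coincidence
TIE_RTOL = 1e-12


@dataclass
class PPSummary:
    """One statistic's posterior predictive comparison for one dataset."""

    name: str
    observed: float
    p_midpoint_lower: float
    effect_size: float  # inf when sd = 0 and the observed value differs
    S: int

    @property
    def p_two_tailed(self) -> float:
        """Convenience two-tailed value min(p, 1-p); not used by any
        decision logic here."""
        return min(self.p_midpoint_lower, 1.0 - self.p_midpoint_lower)


@dataclass
class DistributionSummary:
    """Expected-distribution characterisation of one statistic's
    P-values across replicate datasets."""

    name: str
    pvalues: np.ndarray
    effect_sizes: np.ndarray
    histogram: np.ndarray
    bin_edges: np.ndarray
    mean: float
    variance: float
    ks_stat: float
    ks_pvalue: float | None
    n_undefined: int
    n: int = field(default=0)


def midpoint_pvalue(observed: float, predictive) -> float:
    """Lower one-tailed midpoint P-value of ``observed`` within the
    predictive sample.

    Ties are detected exactly for integer-valued statistics and within
    ``1e-12`` relative tolerance for continuous ones.
    """
    predictive = np.asarray(predictive, dtype=float)
    if predictive.size == 0:
        raise ValueError("predictive sample is empty")
    if math.isnan(observed):
        return float("nan")
    tol = TIE_RTOL * max(abs(observed), 1e-300)
    ties = np.abs(predictive - observed) <= np.maximum(
        tol, TIE_RTOL * np.abs(predictive))
    below = (predictive < observed) & ~ties
    return float((below.sum() + 0.5 * ties.sum()) / predictive.size)


def effect_size(observed: float, predictive) -> float:
    """Posterior predictive effect size
    ``|observed - median| / sd`` (sd with denominator S - 1).

    Returns 0 when the predictive sample is constant and equals the
    observed value, and ``inf`` (flagged-infinite) when it is constant
    but differs; such values are excluded from quantile summaries and
    counted.
    """
    predictive = np.asarray(predictive, dtype=float)
    if predictive.size < 2:
        raise ValueError("need at least 2 predictive values")
    if math.isnan(observed):
        return float("nan")
    num = abs(observed - float(np.median(predictive)))
    sd = float(predictive.std(ddof=1))
    if sd == 0.0:
        return 0.0 if num == 0.0 else float("inf")
    return num / sd


def summarize_stat(name: str, observed: float, predictive) -> PPSummary:
    """Bundle one statistic's observed value, midpoint P-value and
    effect size."""
    predictive = np.asarray(predictive, dtype=float)
    defined = predictive[~np.isnan(predictive)]
    if defined.size == 0 or math.isnan(observed):
        return PPSummary(name, observed, float("nan"), float("nan"),
                         int(defined.size))
    return PPSummary(name, observed,
                     midpoint_pvalue(observed, defined),
                     effect_size(observed, defined) if defined.size >= 2
                     else float("nan"),
                     int(defined.size))


def aggregate(summaries) -> DistributionSummary:
    """Characterise the distribution of replicate P-values for one
    statistic: 20-bin histogram on [0, 1], moments, and a one-sample
    Kolmogorov–Smirnov comparison against Uniform(0, 1).

    The asymptotic KS P-value is reported only for 50 or more defined
    replicates.  Replicates with undefined (NaN) P-values are excluded
    and counted.
    """
    summaries = list(summaries)
    if len(summaries) < 2:
        raise ValueError("need at least 2 replicates to aggregate")
    name = summaries[0].name
    p = np.sort(np.array([s.p_midpoint_lower for s in summaries]))
    es = np.array([s.effect_size for s in summaries])
    defined = p[~np.isnan(p)]
    n_undef = int(np.isnan(p).sum())
    hist, edges = np.histogram(defined, bins=20, range=(0.0, 1.0))
    ks = sps.kstest(defined, "uniform") if defined.size else None
    return DistributionSummary(
        name=name,
        pvalues=defined,
        effect_sizes=es[np.isfinite(es)],
        histogram=hist,
        bin_edges=edges,
        mean=float(defined.mean()) if defined.size else float("nan"),
        variance=float(defined.var(ddof=1)) if defined.size > 1
        else float("nan"),
        ks_stat=float(ks.statistic) if ks else float("nan"),
        ks_pvalue=float(ks.pvalue) if ks and defined.size >= 50 else None,
        n_undefined=n_undef,
        n=int(defined.size),
    )


def statistic_correlations(pvalue_frame):
    """Spearman rank correlations between statistics' replicate
    P-values (pairwise-complete over defined entries).

    ``pvalue_frame`` is a replicate-by-statistic table (DataFrame or
    2-D array).  Constant columns yield NaN correlations.
    """
    import pandas as pd

    frame = pd.DataFrame(pvalue_frame)
    if frame.shape[0] < 3 or frame.shape[1] < 2:
        raise ValueError("need >= 3 replicates and >= 2 statistics")
    return frame.corr(method="spearman")
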