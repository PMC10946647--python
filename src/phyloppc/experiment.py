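"""Config-driven orchestration of the full predictive-check pipeline.

One *replicate* is: draw a generating state (tree + substitution
parameters) from the priors, simulate an observed alignment, fit the
matching model by MCMC, simulate predictive datasets, compute the test
statistics on observed and predictive data, and reduce to a midpoint
P-value and effect size per statistic.  Replicates aggregate into
expected-distribution summaries per statistic.

Five canonical simulation settings are built in (substitution model,
taxa, sites, mean branch length):

====  ========  ====  =====  ==================
 1    JC          16    100  0.1  (baseline)
 2    JC          64    100  0.1
 3    JC          16  1,000  0.1
 4    JC          16    100  0.02
 5    GTR+G+I     16    100  0.1
====  ========  ====  =====  ==================

Each replicate derives its random stream deterministically from the
master seed and its index, so runs are reproducible and resumable
replicate by replicate.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from phyloppc.mcmc import MCMCConfig, mcmc_run
from phyloppc.predictive import (
    DEFAULT_S_DATA,
    DEFAULT_S_INFERENCE,
    fixed_predictive,
    posterior_predictive,
    prior_predictive,
)
from phyloppc.simulate import simulate_alignment
from phyloppc.stats import (
    DATA_STATISTICS,
    INFERENCE_STATISTICS,
    compute_data_statistics,
    compute_inference_statistics,
)
from phyloppc.substitution import GTR_GI, JC, PriorSpec, draw_model_params
from phyloppc.summary import aggregate, statistic_correlations, summarize_stat
from phyloppc.trees import sample_branch_lengths, sample_topology

__all__ = ["SETTINGS", "ExperimentConfig", "ExperimentResult",
           "run_experiment", "setting_spec"]

#: setting -> (model flavor, n_taxa, n_sites, branch-length prior rate)
SETTINGS = {
    1: (JC, 16, 100, 10.0),
    2: (JC, 64, 100, 10.0),
    3: (JC, 16, 1000, 10.0),
    4: (JC, 16, 100, 50.0),
    5: (GTR_GI, 16, 100, 10.0),
}


def setting_spec(setting: int):
    """(PriorSpec, n_sites) for one of the five canonical settings."""
    if setting not in SETTINGS:
        raise ValueError(f"setting must be 1..5, got {setting}")
    flavor, n_taxa, n_sites, bl_rate = SETTINGS[setting]
    return PriorSpec(n_taxa=n_taxa, bl_rate=bl_rate,
                     model_flavor=flavor), n_sites


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment.

    ``setting`` picks a canonical condition; ``prior``/``n_sites``
    override it.  ``s_predictive`` defaults to 1,001 for data-based
    statistic sets and 501 for inference-based ones.  ``statistics`` is
    ``data_based``, ``inference_based`` or ``both``; ``pvalue_source``
    is ``posterior``, ``prior`` or ``fixed``.
    """

    setting: int = 1
    prior: PriorSpec | None = None
    n_sites: int | None = None
    n_datasets: int = 100
    s_predictive: int | None = None
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    predictive_mcmc: MCMCConfig | None = None
    statistics: str = "data_based"
    pvalue_source: str = "posterior"
    seed: int = 0
    out_dir: str | None = None

    def resolved(self):
        spec, n_sites = (setting_spec(self.setting) if self.prior is None
                         else (self.prior, None))
        if self.n_sites is not None:
            n_sites = self.n_sites
        if n_sites is None:
            raise ValueError("n_sites required with an explicit prior")
        S = self.s_predictive
        if S is None:
            S = (DEFAULT_S_INFERENCE if self.statistics == "inference_based"
                 else DEFAULT_S_DATA)
        if self.statistics not in ("data_based", "inference_based", "both"):
            raise ValueError(f"unknown statistic set {self.statistics!r}")
        if self.pvalue_source not in ("posterior", "prior", "fixed"):
            raise ValueError(f"unknown P-value source {self.pvalue_source!r}")
        pmc = self.predictive_mcmc
        if pmc is None:
            # shortened per-predictive-dataset analyses (declared scale
            # parameter for the inference-based step)
            pmc = MCMCConfig(burnin_iters=100, sample_iters=500, thin=5,
                             tune_during_sampling=False)
        return spec, n_sites, S, pmc

    def config_hash(self) -> str:
        def enc(o):
            if isinstance(o, PriorSpec) or isinstance(o, MCMCConfig):
                return asdict(o)
            raise TypeError(str(type(o)))

        payload = json.dumps(asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    replicates: pd.DataFrame      # long: replicate, statistic, observed, p, es
    pvalues: pd.DataFrame         # wide: replicate x statistic
    effect_sizes: pd.DataFrame    # wide: replicate x statistic
    summaries: dict               # statistic -> DistributionSummary
    out_dir: Path | None = None

    def correlations(self) -> pd.DataFrame:
        return statistic_correlations(self.pvalues)


def _replicate_rng(master_seed: int, rep: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(rep,))
    return np.random.default_rng(ss)


def run_replicate(cfg: ExperimentConfig, rep: int) -> list:
    """Run one replicate; returns long-format result rows."""
    spec, n_sites, S, pmc = cfg.resolved()
    rng = _replicate_rng(cfg.seed, rep)
    topo = sample_topology(spec.n_taxa, rng)
    tree = sample_branch_lengths(topo, spec.bl_rate, rng)
    params = draw_model_params(spec, rng)
    observed = simulate_alignment(tree, params, n_sites, rng)

    want_data = cfg.statistics in ("data_based", "both")
    want_inf = cfg.statistics in ("inference_based", "both")

    trace = None
    if cfg.pvalue_source == "posterior" or want_inf:
        trace = mcmc_run(observed, spec, cfg.mcmc, rng)
    if cfg.pvalue_source == "posterior":
        pred = posterior_predictive(trace, n_sites, S, rng)
    elif cfg.pvalue_source == "prior":
        pred = prior_predictive(spec, n_sites, S, rng)
    else:
        pred = fixed_predictive((tree, params), n_sites, S, rng)

    rows = []
    if want_data:
        obs = compute_data_statistics(observed)
        pred_vals = {k: np.empty(S) for k in DATA_STATISTICS}
        for j, d in enumerate(pred.datasets):
            for k, v in compute_data_statistics(d).items():
                pred_vals[k][j] = v
        for k in DATA_STATISTICS:
            s = summarize_stat(k, obs[k], pred_vals[k])
            rows.append((rep, k, s.observed, s.p_midpoint_lower,
                         s.effect_size, s.S))
    if want_inf:
        obs = compute_inference_statistics(trace)
        pred_vals = {k: np.empty(S) for k in INFERENCE_STATISTICS}
        for j, d in enumerate(pred.datasets):
            ptrace = mcmc_run(d, spec, pmc, rng)
            for k, v in compute_inference_statistics(ptrace).items():
                pred_vals[k][j] = v
        for k in INFERENCE_STATISTICS:
            s = summarize_stat(k, obs[k], pred_vals[k])
            rows.append((rep, k, s.observed, s.p_midpoint_lower,
                         s.effect_size, s.S))
    return rows


_COLUMNS = ["replicate", "statistic", "observed", "p_midpoint_lower",
            "effect_size", "S"]


def run_experiment(cfg: ExperimentConfig, progress: bool = False
                   ) -> ExperimentResult:
    """Run all replicates (resuming any previous partial run in
    ``cfg.out_dir``) and aggregate the expected distributions.

    Artifacts written when ``out_dir`` is set: ``manifest.json``
    (config + hash), ``replicates.tsv`` (long format, appended per
    replicate), ``pvalues.tsv`` / ``effect_sizes.tsv`` (wide),
    ``summary.tsv`` and ``correlations.tsv``.
    """
    out = Path(cfg.out_dir) if cfg.out_dir else None
    done: dict = {}
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        manifest = out / "manifest.json"
        if manifest.exists():
            recorded = json.loads(manifest.read_text())
            if recorded.get("config_hash") != cfg.config_hash():
                raise RuntimeError(
                    f"refusing to resume into {out}: existing manifest has "
                    f"config hash {recorded.get('config_hash')} but this "
                    f"configuration hashes to {cfg.config_hash()}")
        else:
            manifest.write_text(json.dumps(
                {"config_hash": cfg.config_hash(),
                 "created": time.strftime("%Y-%m-%dT%H:%M:%S")}, indent=2))
        rep_path = out / "replicates.tsv"
        if rep_path.exists():
            prev = pd.read_csv(rep_path, sep="\t")
            for rep, grp in prev.groupby("replicate"):
                done[int(rep)] = [tuple(r) for r in grp[_COLUMNS].
                                  itertuples(index=False)]

    all_rows = []
    for rep in range(cfg.n_datasets):
        if rep in done:
            all_rows.extend(done[rep])
            continue
        rows = run_replicate(cfg, rep)
        all_rows.extend(rows)
        if out is not None:
            frame = pd.DataFrame(rows, columns=_COLUMNS)
            rep_path = out / "replicates.tsv"
            frame.to_csv(rep_path, sep="\t", index=False, mode="a",
                         header=not rep_path.exists())
        if progress:
            print(f"replicate {rep + 1}/{cfg.n_datasets} done", flush=True)

    long = pd.DataFrame(all_rows, columns=_COLUMNS)
    pvals = long.pivot(index="replicate", columns="statistic",
                       values="p_midpoint_lower")
    esizes = long.pivot(index="replicate", columns="statistic",
                        values="effect_size")

    summaries = {}
    if cfg.n_datasets >= 2:
        from phyloppc.summary import PPSummary

        for stat in pvals.columns:
            grp = long[long.statistic == stat]
            ss = [PPSummary(stat, r.observed, r.p_midpoint_lower,
                            r.effect_size, int(r.S))
                  for r in grp.itertuples(index=False)]
            summaries[stat] = aggregate(ss)

    if out is not None:
        pvals.to_csv(out / "pvalues.tsv", sep="\t")
        esizes.to_csv(out / "effect_sizes.tsv", sep="\t")
        if summaries:
            srows = [{
                "statistic": k, "n": v.n, "mean_p": v.mean,
                "var_p": v.variance, "ks_stat": v.ks_stat,
                "ks_pvalue": v.ks_pvalue if v.ks_pvalue is not None
                else float("nan"),
                "n_undefined": v.n_undefined,
            } for k, v in summaries.items()]
            pd.DataFrame(srows).to_csv(out / "summary.tsv", sep="\t",
                                       index=False)
            if pvals.shape[1] >= 2 and pvals.shape[0] >= 3:
                statistic_correlations(pvals).to_csv(
                    out / "correlations.tsv", sep="\t")

    return ExperimentResult(cfg, long, pvals, esizes, summaries, out)
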