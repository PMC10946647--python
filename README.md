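# phyloppc

Expected distributions of posterior predictive P-values and effect
sizes in Bayesian phylogenetics, computed by simulation under a
*matched* model: data are simulated with parameters drawn from the
priors, the identical model is fitted back by MCMC, and posterior
predictive checks are run on every replicate.

## Why

Posterior predictive checks compare an observed alignment `y` to
datasets `y_rep` simulated from posterior parameter draws, through a
test statistic `T`. The reported tail area

    p = Pr(T(y_rep) < T(y) | y)

is *not* a frequentist P-value: because the model has been fitted to
`y`, its expected distribution under a perfectly adequate model is
generally non-uniform and concentrated around 0.5. Only *ancillary*
statistics — those whose sampling distribution does not depend on the
model parameters, such as GC-content summaries under Jukes–Cantor —
are expected to give uniform P-values. `phyloppc` makes these expected
distributions computable: it quantifies how rare a small P-value
actually is when model and data-generating process agree exactly, which
is what an empirical P-value must be judged against.

The package is aimed at researchers using posterior prediction for
model adequacy in phylogenetics, and at anyone wanting a compact,
fully tested Bayesian phylogenetic MCMC to experiment with.

## What is inside

* **Models** — Jukes–Cantor and GTR+Γ+I (4 discrete Gamma categories,
  proportion of invariable sites), with the standard priors: uniform
  topology, i.i.d. Exponential branch lengths, flat Dirichlets on base
  frequencies and exchangeabilities, Exponential(0.05) on the Gamma
  shape, Beta(10, 20) on the invariable proportion.
* **Simulator** — uniform random topologies, Exponential branch
  lengths, site-wise simulation along the tree (`phyloppc.trees`,
  `phyloppc.simulate`); FASTA/NEXUS/Newick I/O (`phyloppc.seqio`).
* **Inference** — Felsenstein-pruning likelihood with site-pattern
  compression and compiled kernels, Metropolis–Hastings over topology
  (NNI, SPR), branch lengths and substitution parameters, with
  weight-proportional move scheduling and acceptance-rate auto-tuning
  (`phyloppc.likelihood`, `phyloppc.mcmc`).
* **Predictive checks** — posterior/prior/fixed-parameter predictive
  dataset generation (`phyloppc.predictive`); 11 data-based and 9
  inference-based test statistics (`phyloppc.stats`); lower one-tailed
  midpoint P-values, effect sizes `|T(y) − median| / sd`, and
  expected-distribution summaries (`phyloppc.summary`).
* **Orchestration** — five canonical simulation conditions (baseline:
  JC / 16 taxa / 100 sites / mean branch length 0.1; variants with 64
  taxa, 1,000 sites, mean branch length 0.02, or GTR+Γ+I), seeded,
  resumable, with TSV outputs (`phyloppc.experiment`) and a
  `phyloppc` command-line wrapper.

## Worked example

Twenty matched-model replicates of the baseline condition, 100
posterior predictive datasets each:

```python
import numpy as np
from phyloppc.experiment import ExperimentConfig, run_experiment
from phyloppc.mcmc import MCMCConfig

cfg = ExperimentConfig(
    setting=1, n_datasets=20, s_predictive=100,
    mcmc=MCMCConfig(burnin_iters=200, sample_iters=1000, thin=10),
    statistics="data_based", pvalue_source="posterior", seed=42)
res = run_experiment(cfg)
for stat in ("n_invariant_sites", "mean_gc", "var_gc"):
    s = res.summaries[stat]
    print(f"{stat:20s} mean_p={s.mean:.3f}  var_p={s.variance:.4f}  "
          f"KS={s.ks_stat:.3f}")
es = res.effect_sizes.to_numpy().ravel(); es = es[np.isfinite(es)]
print("pooled effect-size 95th percentile: %.3f" % np.percentile(es, 95))
```

prints

```
n_invariant_sites    mean_p=0.515  var_p=0.0644  KS=0.125
mean_gc              mean_p=0.495  var_p=0.0758  KS=0.110
var_gc               mean_p=0.474  var_p=0.0965  KS=0.160
pooled effect-size 95th percentile: 1.537
```

Read: P-values centre on 0.5 for every statistic, but the
non-ancillary invariant-sites statistic is *concentrated* (variance
0.064, well below the uniform 1/12 ≈ 0.083), while the ancillary GC
statistics stay close to uniform (var_gc variance 0.097). Effect sizes
under the matched model stay small — 95% below ≈1.5.

The same run from a shell:

```sh
phyloppc run --setting 1 --n-datasets 20 --s-predictive 100 \
    --iters 1000 --burnin 200 --thin 10 --seed 42 --out results/demo
```

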