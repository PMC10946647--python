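# Methods

This note records the model, the algorithmic conventions, and the
design choices behind `phyloppc`, in enough detail to re-derive every
number the package produces.

## Model and priors

Data are DNA alignments over `{A, C, G, T}` (no gaps or ambiguity —
this is a simulated-data study). Sites evolve independently along an
unrooted labelled binary tree under a time-reversible substitution
model:

* **JC** — equal base frequencies and exchangeabilities, a single rate
  category, no invariable class;
* **GTR+Γ+I** — free frequencies `π` (order A, C, G, T) and
  exchangeabilities `er` (order AC, AG, AT, CG, CT, GT), Gamma rate
  variation discretised into 4 categories, and a proportion `I` of
  invariable sites.

Priors (shared by the simulator and the sampler — the matched-model
design):

| parameter | prior | value |
|---|---|---|
| topology Ψ | uniform over the (2n−5)!! unrooted binary trees | n = 16 or 64 |
| branch lengths | i.i.d. Exponential(λ_bl) | λ_bl = 10 or 50 |
| π | Dirichlet(1,1,1,1) | |
| er | Dirichlet(1,…,1) | |
| Γ shape α | Exponential(λ_α) | λ_α = 0.05 |
| I | Beta(α_I, β_I) | (10, 20) |

The five canonical conditions vary one factor at a time around the
baseline (JC, 16 taxa, 100 sites, mean branch length 0.1): 64 taxa,
1,000 sites, mean branch length 0.02, or GTR+Γ+I.

### Numerical conventions

* The GTR rate matrix `Q_ij = er_ij π_j` is normalised to mean rate 1
  at stationarity. The **invariable class is excluded from the
  normalisation**: branch lengths are expected substitutions per
  variable-process site. This matches common practice; the opposite
  convention (normalising the full mixture) would rescale branch
  lengths by 1/(1−I) but leave P-values of the matched study
  unchanged, because simulator and sampler share the convention.
* Γ discretisation uses **equal category probabilities and the mean of
  each inter-quantile interval** (not the median), computed through
  regularised incomplete gamma functions; this keeps the mixture mean
  exactly 1 for every shape.
* JC transition probabilities use the closed form
  `P_ii = 1/4 + 3/4 e^(−4d/3)`; GTR uses the symmetric
  eigendecomposition `B = D^{1/2} Q D^{−1/2}` so `eigh` applies.
* Pruning partials are rescaled per pattern when they drop below
  1e−40, with the log scale accumulated, so 64-taxon likelihoods stay
  in range; a site likelihood of exactly zero (possible only in
  degenerate zero-length configurations) is floored at 1e−300 before
  the log.
* Trees are stored rooted at an arbitrary internal node of degree 3
  ("virtual root") purely as a data-structure convention; all models
  are reversible, so the likelihood is root-invariant (asserted by
  test).

## Simulator

Topologies are drawn by sequential random addition (each new leaf
attaches to a uniformly chosen edge), which is exactly uniform over
labelled unrooted binary shapes. Per site, a rate class is drawn
(rate 0 with probability I, else one of the 4 category rates), the
root state from `π`, and states propagate through per-edge transition
matrices. Same seed ⇒ byte-identical alignment.

## MCMC

Metropolis–Hastings with weight-proportional random scan: one
iteration performs `round(Σ weights)` single-move attempts, each move
chosen with probability `weight / Σ weights`. Default weights: NNI and
single-branch multiplier at `n_taxa`, SPR at `0.1 n_taxa`; GTR+Γ+I
adds Beta/Dirichlet simplex proposals on π (2.0 / 1.0) and er
(3.0 / 1.5), a multiplier on α (2.0) and a Beta-centred proposal on I
(2.0). JC analyses use only the first three moves. The weight schedule
is inherited from standard practice; random scan is used because it
preserves the stationary distribution unambiguously.

Branch lengths (and their cached transition matrices) are attached to
nodes and travel with them, so NNI and SPR are pure pointer surgery:
the multiset of branch lengths is invariant, the topology prior is
uniform, and both moves reduce to likelihood-ratio Metropolis steps.
NNI picks a uniform internal edge and one of its two subtree
exchanges. SPR first moves the virtual root to a uniformly chosen
internal node — this makes the proposal symmetric over unrooted trees
(the count of internal nodes outside the pruned subtree is preserved
by the move) — then prunes a uniform non-root subtree and regrafts it
to a uniform eligible edge, where the dissolved attachment node
carries its branch length along; proposals with no eligible target
count as rejections.

Scalar proposals: multiplier `exp(λ(u − 1/2))` with log-Hastings
`log m` for branch lengths and α; Beta-centred proposals
`Beta(δx + 1, δ(1−x) + 1)` for I and for single simplex elements (with
the remaining elements rescaled; Jacobian `(K−2) log scale`); whole-
simplex proposals from `Dirichlet(δx + 1)`. The `+1` offsets keep the
proposal densities bounded away from degenerate corners. Exact
forward/reverse density corrections are used throughout; prior ratios
are computed analytically per move.

Auto-tuning targets acceptance ≈ 0.44: every `tune_interval`
iterations (200 by default; during burn-in, and during sampling when
configured) each tunable parameter is multiplied (step-size type) or
divided (concentration type) by `exp(clip(acc − 0.44, −0.5, 0.5))`,
with hard clamps. The specific rule is a design choice; correctness is
asserted against the priors, not against any external sampler, via
the constant-likelihood (prior-recovery) tests.

Chains start from a prior draw (always finite posterior), default to
`thin = sample_iters / 200` (≈200 retained draws at any scale), and
support a two-replicate mode that concatenates post-burn-in samples of
independent chains.

## Predictive checks

Posterior predictive datasets are simulated from evenly spaced thinned
trace indices (lower variance than i.i.d. resampling; an `iid` mode
exists for sensitivity checks); prior predictive from i.i.d. prior
draws; fixed-parameter predictive from a single supplied state. All
three share one simulation kernel. Default sample sizes are 1,001
(data-based) and 501 (inference-based) predictive datasets,
overridable.

### Statistics

Data-based (11): number of invariant sites, longest invariant and
variable blocks, min/max scaled pairwise difference, mean and variance
of GC content, Watterson's θ, Tajima's D and π, multinomial
log-likelihood of site-pattern frequencies. Conventions: "scaled"
pairwise differences are mismatch proportions (the only scale-free
reading); θ and π are per-alignment counts (midpoint P-values are
invariant to any monotone rescaling shared by observed and predictive
values, so per-site versions would give identical results); Tajima's D
is undefined at zero segregating sites and such replicates are
excluded and counted, never imputed.

Inference-based (9): mean and ordered-vector quantiles (25/50/75/99th
percentile and the 999th 1,000-quantile) of Robinson–Foulds distances
between sampled trees, the topology information gain, and the mean and
variance of tree length. The RF pair set is all unordered pairs up to
200 trees, else a fixed-seed subsample of 20,000 pairs; quantiles take
element `ceil(q·m)` (1-indexed) of the sorted vector. The information
gain is `ln((2n−5)!!) + Σ f̂ ln f̂` — prior minus empirical posterior
Shannon entropy, natural log — so a trace of m all-distinct topologies
gives the constant `ln((2n−5)!!) − ln m`. These two definitions are
declared conventions (isolated behind the statistic registry so
alternatives can be swapped in).

### Summaries

The reported P-value is the lower one-tailed midpoint value
`(#{T_rep < T_obs} + ½#{T_rep = T_obs}) / S`, with ties detected
exactly for integer statistics and at 1e−12 relative tolerance for
continuous ones (independent simulations tie only through
floating-point coincidence). A two-tailed `min(p, 1−p)` is emitted for
convenience but drives no logic. Effect size is
`|T_obs − median(T_rep)| / sd(T_rep)` (sd with denominator S−1); a
zero-sd predictive sample gives 0 on equality and a flagged infinity
otherwise, excluded from quantile summaries and counted.

Aggregation across replicates yields a 20-bin histogram on [0, 1],
moments, and an asymptotic one-sample KS test against Uniform(0, 1)
(P-value reported only for n ≥ 50). Cross-statistic association uses
Spearman rank correlation, pairwise-complete over defined entries.

## Experiment design and problem sizes

Each replicate derives its generator from
`SeedSequence(master_seed, spawn_key=(replicate,))`, so replicates are
independently reproducible and runs are resumable replicate by
replicate (a config-hash manifest refuses to resume a different
configuration).

The production-scale design (10,000 replicates for data-based
statistics, 1,000 for inference-based; MCMC of 200 burn-in + 10,000
sampling iterations) is cluster-sized. The package runs the same
design at configurable scale; the default acceptance/desk scale is
**100 replicates, MCMC 200 + 1,000 iterations thinned to 100 draws,
100 predictive datasets per replicate**, which reproduces the
qualitative expectations (concentration of non-ancillary P-values,
uniformity of ancillary ones, effect sizes below 2) in a few CPU
minutes. Per-predictive-dataset MCMC for inference-based statistics
defaults to a shortened 100 + 500 iteration analysis — a declared
scale parameter, not a silent change.

## What the synthetic data does and does not cover

The generator *is* the study design: matched model, parameters from
the priors. It does not emulate empirical-data features — indels,
alignment error, compositional heterogeneity across lineages,
site-dependence, partitioned structure. Passing tests therefore
establish the behaviour of the checks under a correctly specified
model, the null reference for interpreting empirical P-values; they
say nothing about any specific empirical misfit pattern.

## Known limitations

* The maximum-likelihood parametric-bootstrap variant of the check is
  out of scope (it needs an ML phylogenetic optimiser).
* No convergence diagnostics beyond acceptance tallies; the study
  regime (small matched datasets, prior starts) mixes quickly, and the
  prior-recovery suite is the correctness surface.
* Proposal parameterisations for the simplex moves and the tuning rule
  are this package's own (documented above); no bit-compatibility with
  any other sampler is claimed.
* `mean_gc` ancillarity under JC is exact only marginally (the
  GC/AT collapse of JC is a symmetric two-state chain whose
  correlation structure depends on the tree); at the study's scales
  the dependence is far below detectability, and the expected P-value
  distribution is uniform in practice.
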