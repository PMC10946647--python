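"""Metropolis–Hastings MCMC over tree topology, branch lengths and
substitution-model parameters.

The move set mirrors the standard phylogenetic repertoire: NNI and SPR
on the topology, a multiplier move on single branch lengths, Beta- and
Dirichlet-centred proposals on the frequency/exchangeability simplices,
a multiplier on the Gamma shape and a Beta-centred proposal on the
proportion of invariable sites.  JC analyses use only the first three.

Scheduling is weight-proportional random scan: each iteration performs
``round(sum of weights)`` single-move attempts, each move drawn with
probability proportional to its weight.  Tuning parameters are adapted
multiplicatively towards a ~0.44 acceptance rate every
``tune_interval`` iterations during burn-in (and, optionally, during
sampling).

Topology bookkeeping: branch lengths (and hence transition matrices)
are attached to nodes and travel with them, so NNI/SPR change only the
parent/child pointers; the multiset of branch lengths is invariant
under both moves and the topology prior is uniform, so their
Metropolis–Hastings ratio reduces to the likelihood ratio.  Before each
SPR the virtual root is moved to a uniformly chosen internal node,
which makes the proposal symmetric over unrooted trees.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from phyloppc import _kernels
from phyloppc.likelihood import LikelihoodEngine, PatternTable, compress_patterns
from phyloppc.simulate import Alignment
from phyloppc.substitution import (
    GTR_GI,
    JC,
    ModelParams,
    PriorSpec,
    discretize_gamma,
    draw_model_params,
    eigensystem,
)
from phyloppc.trees import PhyloTree, sample_branch_lengths, sample_topology

__all__ = ["MCMCConfig", "PosteriorTrace", "mcmc_run", "apply_move",
           "default_move_weights", "log_prior"]

TOPOLOGY_MOVES = ("nni", "spr")
BRANCH_MOVES = ("branch_scale",)
PARAM_MOVES = ("pi_beta_simplex", "pi_dirichlet_simplex", "er_beta_simplex",
               "er_dirichlet_simplex", "shape_scale", "pinv_beta")

#: moves whose tuning parameter is a step-size multiplier (bigger value
#: means bigger steps) vs. a proposal concentration (bigger means
#: smaller steps)
_SCALE_TUNED = {"branch_scale": 1.0, "shape_scale": 1.0}
_CONC_TUNED = {"pi_beta_simplex": 50.0, "pi_dirichlet_simplex": 100.0,
               "er_beta_simplex": 50.0, "er_dirichlet_simplex": 100.0,
               "pinv_beta": 20.0}


def default_move_weights(spec: PriorSpec) -> dict:
    """Default per-move weights: NNI and the branch-length multiplier at
    weight ``n_taxa``, SPR at ``0.1 * n_taxa``; GTR+Gamma+I additionally
    perturbs the base frequencies (2.0 / 1.0 for the Beta / Dirichlet
    proposal), exchangeabilities (3.0 / 1.5), Gamma shape (2.0) and
    invariable proportion (2.0)."""
    w = {"nni": float(spec.n_taxa), "spr": 0.1 * spec.n_taxa,
         "branch_scale": float(spec.n_taxa)}
    if spec.model_flavor == GTR_GI:
        w.update({"pi_beta_simplex": 2.0, "pi_dirichlet_simplex": 1.0,
                  "er_beta_simplex": 3.0, "er_dirichlet_simplex": 1.5,
                  "shape_scale": 2.0, "pinv_beta": 2.0})
    return w


@dataclass
class MCMCConfig:
    """Sampler configuration.

    ``thin`` defaults to ``max(1, sample_iters // 200)`` so a trace
    holds about 200 draws at any scale.  ``replicates > 1`` runs
    independent chains (fresh prior draws, independent random streams)
    and concatenates their post-burn-in samples.
    """

    burnin_iters: int = 200
    sample_iters: int = 10_000
    thin: int | None = None
    tune_interval: int = 200
    tune_during_sampling: bool = True
    move_weights: dict | None = None
    seed: int | None = None
    replicates: int = 1

    def resolved_thin(self) -> int:
        if self.thin is not None:
            if self.thin < 1:
                raise ValueError("thin must be positive")
            return self.thin
        return max(1, self.sample_iters // 200)

    def resolved_weights(self, spec: PriorSpec) -> dict:
        w = dict(default_move_weights(spec) if self.move_weights is None
                 else self.move_weights)
        if any(v < 0 for v in w.values()):
            raise ValueError("move weights must be nonnegative")
        bad = [m for m in w if m in PARAM_MOVES and w[m] > 0
               and spec.model_flavor == JC]
        if bad:
            raise ValueError(
                f"moves {bad} are not applicable under JC (no free "
                "substitution parameters)")
        if not any(w.get(m, 0) > 0 for m in TOPOLOGY_MOVES):
            raise ValueError("need a topology move with positive weight")
        if not any(w.get(m, 0) > 0 for m in BRANCH_MOVES):
            raise ValueError("need a branch-length move with positive weight")
        return {m: v for m, v in w.items() if v > 0}


@dataclass
class PosteriorTrace:
    """Sampled states of one (possibly multi-replicate) MCMC analysis."""

    taxa: list
    trees: list
    params: list
    log_posteriors: np.ndarray
    iterations: np.ndarray
    acceptance: dict
    tuning: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.trees)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def tree_lengths(self) -> np.ndarray:
        return np.array([t.tree_length() for t in self.trees])

    def scalar_frame(self):
        """Scalar parameters and log posterior, one row per sample."""
        import pandas as pd

        rows = []
        for it, tr, pa, lp in zip(self.iterations, self.trees, self.params,
                                  self.log_posteriors):
            row = {"iteration": int(it), "log_posterior": lp,
                   "tree_length": tr.tree_length(),
                   "shape": pa.shape, "pinv": pa.pinv}
            for i, b in enumerate("ACGT"):
                row[f"pi_{b}"] = pa.pi[i]
            for i, pair in enumerate(("AC", "AG", "AT", "CG", "CT", "GT")):
                row[f"er_{pair}"] = pa.er[i]
            rows.append(row)
        return pd.DataFrame(rows)


def _log_dfact(m: int) -> float:
    """log of the odd double factorial m!! (m odd)."""
    return sum(math.log(k) for k in range(3, m + 1, 2))


def log_prior(spec: PriorSpec, tree: PhyloTree, params: ModelParams) -> float:
    """Joint log prior density of a full model state."""
    n = spec.n_taxa
    lp = -_log_dfact(2 * n - 5)  # uniform over unrooted topologies
    lens = np.delete(tree.lengths, tree.root)
    lp += float(np.sum(np.log(spec.bl_rate) - spec.bl_rate * lens))
    if spec.model_flavor == GTR_GI:
        lp += _dirichlet_logpdf(params.pi, np.asarray(spec.pi_alpha))
        lp += _dirichlet_logpdf(params.er, np.asarray(spec.er_alpha))
        lp += math.log(spec.shape_rate) - spec.shape_rate * params.shape
        a, b = spec.pinv_beta
        lp += ((a - 1) * math.log(params.pinv)
               + (b - 1) * math.log1p(-params.pinv) - _betaln(a, b))
    return lp


def _betaln(a: float, b: float) -> float:
    return math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)


def _beta_logpdf(x: float, a: float, b: float) -> float:
    return ((a - 1) * math.log(x) + (b - 1) * math.log1p(-x)
            - _betaln(a, b))


def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    return float(np.sum((alpha - 1) * np.log(x)) + math.lgamma(alpha.sum())
                 - np.sum([math.lgamma(a) for a in alpha]))


# ----------------------------------------------------------------------
# proposal primitives (shared by the chain and by `apply_move`)
# ----------------------------------------------------------------------
def _nni_swap(tree: PhyloTree, v: int, c: int, d: int) -> None:
    """Exchange subtree ``c`` (child of ``v``) with subtree ``d`` (child
    of ``parent(v)``).  Applying the same swap twice restores the
    original topology."""
    p = tree.parent[v]
    rowv, rowp = tree.childmat[v], tree.childmat[p]
    rowv[np.argmax(rowv[: tree.nchild[v]] == c)] = d
    rowp[np.argmax(rowp[: tree.nchild[p]] == d)] = c
    tree.parent[c] = p
    tree.parent[d] = v


def _nni_choices(tree: PhyloTree, rng: np.random.Generator):
    """Uniform internal edge and one of its two subtree exchanges."""
    n_taxa = tree.n_taxa
    n_int = n_taxa - 2
    if n_int < 2:
        raise ValueError("no internal edge for NNI")
    i = int(rng.integers(n_int - 1))
    v = n_taxa + i
    if v >= tree.root:
        v += 1
    p = tree.parent[v]
    c = int(tree.childmat[v, rng.integers(2)])
    if p == tree.root:
        others = [int(tree.childmat[p, k]) for k in range(3)
                  if tree.childmat[p, k] != v]
        d = others[int(rng.integers(2))]
    else:
        row = tree.childmat[p]
        d = int(row[0]) if row[1] == v else int(row[1])
    return v, c, d


def _spr_detach_regraft(tree: PhyloTree, v: int, u: int) -> None:
    """Move the subtree above-edge at ``v``: dissolve its parent ``p``
    out of its current position and re-insert it into the edge above
    ``u``.  All branch lengths stay attached to their nodes."""
    p = int(tree.parent[v])
    g = int(tree.parent[p])
    rowp = tree.childmat[p]
    s = int(rowp[0]) if rowp[1] == v else int(rowp[1])
    gu = int(tree.parent[u])
    # detach: s takes p's slot under g
    rowg = tree.childmat[g]
    rowg[np.argmax(rowg[: tree.nchild[g]] == p)] = s
    tree.parent[s] = g
    # insert: p takes u's slot under gu; u goes under p
    rowgu = tree.childmat[gu]
    rowgu[np.argmax(rowgu[: tree.nchild[gu]] == u)] = p
    tree.parent[p] = gu
    rowp[np.argmax(rowp[:2] == s)] = u
    tree.parent[u] = p


def _beta_centred_propose(x: float, delta: float, rng: np.random.Generator):
    """Propose on (0,1) from Beta(delta*x + 1, delta*(1-x) + 1); returns
    (proposal, log Hastings) or None if numerically degenerate."""
    a, b = delta * x + 1.0, delta * (1.0 - x) + 1.0
    y = rng.beta(a, b)
    if not (1e-12 < y < 1.0 - 1e-12):
        return None
    logq_f = _beta_logpdf(y, a, b)
    logq_r = _beta_logpdf(x, delta * y + 1.0, delta * (1.0 - y) + 1.0)
    return y, logq_r - logq_f


def _beta_simplex_propose(x: np.ndarray, delta: float,
                          rng: np.random.Generator):
    """Perturb one simplex element via a Beta proposal centred on its
    current value, rescaling the others; returns (new simplex, index,
    log Hastings) or None."""
    K = x.size
    i = int(rng.integers(K))
    prop = _beta_centred_propose(float(x[i]), delta, rng)
    if prop is None:
        return None
    y, logh = prop
    scale = (1.0 - y) / (1.0 - x[i])
    xnew = x * scale
    xnew[i] = y
    # Jacobian of rescaling the K-1 remaining coordinates (K-2 free)
    logh += (K - 2) * math.log(scale)
    return xnew, i, logh


def _dirichlet_simplex_propose(x: np.ndarray, delta: float,
                               rng: np.random.Generator):
    """Propose a whole simplex from Dirichlet(delta * x + 1); returns
    (new simplex, log Hastings) or None."""
    a_f = delta * x + 1.0
    y = rng.dirichlet(a_f)
    if y.min() <= 1e-12:
        return None
    y = y / y.sum()
    a_r = delta * y + 1.0
    logh = _dirichlet_logpdf(x, a_r) - _dirichlet_logpdf(y, a_f)
    return y, logh


# ----------------------------------------------------------------------
# the chain
# ----------------------------------------------------------------------
class _Chain:
    """One MCMC chain; state is updated in place, move by move."""

    def __init__(self, pt: PatternTable | None, spec: PriorSpec,
                 cfg: MCMCConfig, rng: np.random.Generator,
                 taxa: list | None = None):
        self.spec = spec
        self.cfg = cfg
        self.rng = rng
        if pt is not None:
            taxa = pt.taxa
        elif taxa is None:
            taxa = [f"t{i + 1}" for i in range(spec.n_taxa)]
        topo = sample_topology(spec.n_taxa, rng, labels=list(taxa))
        self.tree = sample_branch_lengths(topo, spec.bl_rate, rng)
        self.params = draw_model_params(spec, rng)
        self.n_taxa = spec.n_taxa
        self.n_int = spec.n_taxa - 2
        self.n_nodes = 2 * spec.n_taxa - 2

        self.post = np.empty(self.n_int, np.int32)
        self.post_alt = np.empty(self.n_int, np.int32)
        _kernels.postorder_internal(self.tree.childmat, self.tree.nchild,
                                    self.tree.root, self.n_taxa, self.post)
        self._node_buf = np.empty(1, np.int32)

        self.pt = pt
        if pt is not None:
            self.engine = LikelihoodEngine(pt, self.tree.taxa)
            self.rates = self.params.category_rates()
            if self.params.model_flavor == JC:
                self.catw = np.ones(1)
            else:
                self.catw = np.full(self.rates.size,
                                    (1.0 - self.params.pinv) / self.rates.size)
            self.pmats = self.engine._ensure(self.rates.size)
            self._refill_all_pmats()
            self.ll = self._loglik()
            if not np.isfinite(self.ll) or self.ll < -1e290:
                raise RuntimeError(
                    "initial state has vanishing likelihood; re-seed the "
                    "chain (the start state is drawn from the prior)")
        else:
            self.engine = None
            self.pmats = None
            self.rates = np.ones(1)
            self.catw = np.ones(1)
            self.ll = 0.0

        weights = cfg.resolved_weights(spec)
        self.move_names = list(weights)
        total = sum(weights.values())
        self.n_per_iter = max(1, int(round(total)))
        cum, acc = [], 0.0
        for m in self.move_names:
            acc += weights[m] / total
            cum.append(acc)
        cum[-1] = 1.0
        self._cum = cum
        self._steps = [getattr(self, "_step_" + m) for m in self.move_names]
        self.tuning = dict(_SCALE_TUNED)
        self.tuning.update(_CONC_TUNED)
        k = len(self.move_names)
        self.att = np.zeros(k, np.int64)
        self.acc = np.zeros(k, np.int64)
        self.win_att = np.zeros(k, np.int64)
        self.win_acc = np.zeros(k, np.int64)

    # -- likelihood plumbing -------------------------------------------
    def _loglik(self) -> float:
        if self.pt is None:
            return 0.0
        e = self.engine
        return _kernels.pruning_loglik(
            self.post, self.tree.childmat, self.tree.nchild, self.n_taxa,
            self.pmats, e.tips, e.patw, self.params.pi, self.catw,
            self.params.pinv, e.const_state, e._partials, e._logscale)

    def _refill_all_pmats(self, nodes=None):
        if self.pt is None:
            return
        if nodes is None:
            nodes = self.tree.edge_nodes()
        if self.params.model_flavor == JC:
            _kernels.fill_jc_pmats(nodes, self.tree.lengths, self.rates,
                                   self.pmats)
        else:
            if self.engine._eig is None:
                self.engine._eig = eigensystem(self.params)
            left, w, right = self.engine._eig
            _kernels.fill_gtr_pmats(nodes, self.tree.lengths, self.rates,
                                    left, w, right, self.pmats)

    def _refill_node(self, v: int):
        if self.pt is None:
            return
        self._node_buf[0] = v
        self._refill_all_pmats(self._node_buf)

    def _new_post(self):
        _kernels.postorder_internal(self.tree.childmat, self.tree.nchild,
                                    self.tree.root, self.n_taxa,
                                    self.post_alt)
        self.post, self.post_alt = self.post_alt, self.post

    def _accept(self, logr: float) -> bool:
        return logr >= 0.0 or math.log(self.rng.random()) < logr

    def _random_edge_node(self) -> int:
        i = int(self.rng.integers(self.n_nodes - 1))
        return i if i < self.tree.root else i + 1

    # -- moves ---------------------------------------------------------
    def _step_nni(self) -> bool:
        v, c, d = _nni_choices(self.tree, self.rng)
        _nni_swap(self.tree, v, c, d)
        self._new_post()
        new_ll = self._loglik()
        if self._accept(new_ll - self.ll):
            self.ll = new_ll
            return True
        _nni_swap(self.tree, v, d, c)
        self.post, self.post_alt = self.post_alt, self.post
        return False

    def _reroot_with_pmats(self, new_root: int):
        tree = self.tree
        if new_root == tree.root:
            return
        path = [new_root]
        while path[-1] != tree.root:
            path.append(int(tree.parent[path[-1]]))
        if self.pt is not None:
            saved = {a: self.pmats[a].copy() for a in path[:-1]}
        tree.reroot(new_root)
        if self.pt is not None:
            # lengths moved one step along the path; mirror the matrices
            for a, b in zip(path[:-1], path[1:]):
                self.pmats[b] = saved[a]
        self._new_post()

    def _step_spr(self) -> bool:
        tree, rng = self.tree, self.rng
        new_root = self.n_taxa + int(rng.integers(self.n_int))
        self._reroot_with_pmats(new_root)
        v = self._random_edge_node()
        p = int(tree.parent[v])
        if p == tree.root:
            return False
        sub = set(tree.subtree_nodes(v))
        rowp = tree.childmat[p]
        s = int(rowp[0]) if rowp[1] == v else int(rowp[1])
        targets = [u for u in range(self.n_nodes)
                   if u != tree.root and u != p and u != s and u not in sub]
        if not targets:
            return False
        u = targets[int(rng.integers(len(targets)))]
        _spr_detach_regraft(tree, v, u)
        self._new_post()
        new_ll = self._loglik()
        if self._accept(new_ll - self.ll):
            self.ll = new_ll
            return True
        _spr_detach_regraft(tree, v, s)
        self._new_post()
        return False

    def _step_branch_scale(self) -> bool:
        tree, rng = self.tree, self.rng
        v = self._random_edge_node()
        lam = self.tuning["branch_scale"]
        m = math.exp(lam * (rng.random() - 0.5))
        old = tree.lengths[v]
        tree.lengths[v] = old * m
        if self.pt is not None:
            old_pmat = self.pmats[v].copy()
        self._refill_node(v)
        new_ll = self._loglik()
        logr = (new_ll - self.ll
                - self.spec.bl_rate * (tree.lengths[v] - old)  # Exp prior
                + math.log(m))                                 # Hastings
        if self._accept(logr):
            self.ll = new_ll
            return True
        tree.lengths[v] = old
        if self.pt is not None:
            self.pmats[v] = old_pmat
        return False

    def _try_params(self, new_params: ModelParams, logh: float,
                    dprior: float, refill: bool, new_rates=None,
                    new_catw=None) -> bool:
        """Generic accept/reject for a substitution-parameter proposal."""
        old_params, old_rates, old_catw = self.params, self.rates, self.catw
        old_eig = self.engine._eig if self.engine is not None else None
        if self.pt is not None and refill:
            old_pmats = self.pmats.copy()
        self.params = new_params
        if new_rates is not None:
            self.rates = new_rates
        if new_catw is not None:
            self.catw = new_catw
        if refill and self.engine is not None:
            self.engine._eig = None if new_params.model_flavor == GTR_GI \
                else old_eig
            if (new_params.pi is old_params.pi
                    and new_params.er is old_params.er):
                self.engine._eig = old_eig  # only rates changed
            self._refill_all_pmats()
        new_ll = self._loglik()
        if self._accept(new_ll - self.ll + dprior + logh):
            self.ll = new_ll
            return True
        self.params, self.rates, self.catw = old_params, old_rates, old_catw
        if self.engine is not None:
            self.engine._eig = old_eig
            if refill and self.pt is not None:
                self.pmats[...] = old_pmats
        return False

    def _simplex_step(self, which: str, style: str, tname: str) -> bool:
        x = self.params.pi if which == "pi" else self.params.er
        alpha = np.asarray(self.spec.pi_alpha if which == "pi"
                           else self.spec.er_alpha)
        delta = self.tuning[tname]
        if style == "beta":
            prop = _beta_simplex_propose(x, delta, self.rng)
            if prop is None:
                return False
            xnew, _, logh = prop
        else:
            prop = _dirichlet_simplex_propose(x, delta, self.rng)
            if prop is None:
                return False
            xnew, logh = prop
        dprior = float(np.sum((alpha - 1) * (np.log(xnew) - np.log(x))))
        new_params = self.params.copy()
        if which == "pi":
            new_params.pi = xnew
        else:
            new_params.er = xnew
        return self._try_params(new_params, logh, dprior, refill=True)

    def _step_pi_beta_simplex(self):
        return self._simplex_step("pi", "beta", "pi_beta_simplex")

    def _step_pi_dirichlet_simplex(self):
        return self._simplex_step("pi", "dirichlet", "pi_dirichlet_simplex")

    def _step_er_beta_simplex(self):
        return self._simplex_step("er", "beta", "er_beta_simplex")

    def _step_er_dirichlet_simplex(self):
        return self._simplex_step("er", "dirichlet", "er_dirichlet_simplex")

    def _step_shape_scale(self) -> bool:
        lam = self.tuning["shape_scale"]
        m = math.exp(lam * (self.rng.random() - 0.5))
        new_shape = self.params.shape * m
        new_params = self.params.copy()
        new_params.shape = new_shape
        new_rates = (discretize_gamma(new_shape, new_params.n_categories)
                     if self.pt is not None else None)
        dprior = -self.spec.shape_rate * (new_shape - self.params.shape)
        return self._try_params(new_params, math.log(m), dprior,
                                refill=self.pt is not None,
                                new_rates=new_rates)

    def _step_pinv_beta(self) -> bool:
        prop = _beta_centred_propose(self.params.pinv,
                                     self.tuning["pinv_beta"], self.rng)
        if prop is None:
            return False
        y, logh = prop
        a, b = self.spec.pinv_beta
        x = self.params.pinv
        dprior = ((a - 1) * (math.log(y) - math.log(x))
                  + (b - 1) * (math.log1p(-y) - math.log1p(-x)))
        new_params = self.params.copy()
        new_params.pinv = y
        new_catw = (np.full(self.rates.size, (1.0 - y) / self.rates.size)
                    if self.pt is not None else None)
        return self._try_params(new_params, logh, dprior, refill=False,
                                new_catw=new_catw)

    # -- driver --------------------------------------------------------
    def _tune(self):
        for k, name in enumerate(self.move_names):
            if self.win_att[k] == 0 or name not in self.tuning:
                continue
            rate = self.win_acc[k] / self.win_att[k]
            factor = math.exp(min(0.5, max(-0.5, rate - 0.44)))
            if name in _SCALE_TUNED:
                self.tuning[name] = min(1e3, max(1e-3,
                                                 self.tuning[name] * factor))
            else:
                self.tuning[name] = min(1e7, max(1e-1,
                                                 self.tuning[name] / factor))
        self.win_att[:] = 0
        self.win_acc[:] = 0

    def run(self):
        cfg = self.cfg
        thin = cfg.resolved_thin()
        trees, params, logpost, its = [], [], [], []
        cum = self._cum
        steps = self._steps
        rng = self.rng
        total = cfg.burnin_iters + cfg.sample_iters
        for it in range(total):
            sampling = it >= cfg.burnin_iters
            for _ in range(self.n_per_iter):
                k = bisect_left(cum, rng.random())
                self.att[k] += 1
                self.win_att[k] += 1
                if steps[k]():
                    self.acc[k] += 1
                    self.win_acc[k] += 1
            if (cfg.tune_interval > 0 and (it + 1) % cfg.tune_interval == 0
                    and (not sampling or cfg.tune_during_sampling)):
                self._tune()
            if sampling and (it - cfg.burnin_iters + 1) % thin == 0:
                trees.append(self.tree.copy())
                params.append(self.params.copy())
                logpost.append(self.ll + log_prior(self.spec, self.tree,
                                                   self.params))
                its.append(it + 1)
        acc = {name: (int(self.acc[k]), int(self.att[k]))
               for k, name in enumerate(self.move_names)}
        return trees, params, np.array(logpost), np.array(its, dtype=int), acc


def mcmc_run(aln: Alignment | None, spec: PriorSpec, cfg: MCMCConfig,
             rng: np.random.Generator | None = None) -> PosteriorTrace:
    """Run the MCMC analysis and return the posterior trace.

    ``aln=None`` runs the sampler against a constant likelihood, i.e.
    targets the prior — the standard validation surface for the moves.
    ``cfg.replicates > 1`` concatenates post-burn-in samples of
    independent chains.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pt = compress_patterns(aln) if aln is not None else None
    if pt is not None and len(pt.taxa) != spec.n_taxa:
        raise ValueError(
            f"alignment has {len(pt.taxa)} taxa but the prior specifies "
            f"{spec.n_taxa}")
    child_rngs = rng.spawn(cfg.replicates) if cfg.replicates > 1 else [rng]
    all_trees, all_params, all_lp, all_it = [], [], [], []
    acc_total: dict = {}
    tuning = {}
    taxa = None
    for crng in child_rngs:
        chain = _Chain(pt, spec, cfg, crng)
        trees, params, lp, its, acc = chain.run()
        taxa = chain.tree.taxa
        all_trees += trees
        all_params += params
        all_lp.append(lp)
        all_it.append(its)
        tuning = dict(chain.tuning)
        for name, (a, t) in acc.items():
            a0, t0 = acc_total.get(name, (0, 0))
            acc_total[name] = (a0 + a, t0 + t)
    return PosteriorTrace(
        taxa=list(taxa),
        trees=all_trees,
        params=all_params,
        log_posteriors=np.concatenate(all_lp) if all_lp else np.array([]),
        iterations=np.concatenate(all_it) if all_it else np.array([], int),
        acceptance=acc_total,
        tuning=tuning,
    )


def apply_move(tree: PhyloTree, params: ModelParams, move_name: str,
               tuning: float, rng: np.random.Generator):
    """Apply a single proposal to a copy of the state.

    Returns ``(new_tree, new_params, log_hastings)``; the inputs are not
    modified.  Topology moves have log-Hastings 0; the multiplier moves
    return ``log(multiplier)``; the simplex/probability proposals return
    the exact forward/reverse density correction.  ``None`` is returned
    in place of the proposal when it is numerically degenerate (callers
    should treat that as an immediate rejection).
    """
    t = tree.copy()
    p = params.copy()
    if move_name == "nni":
        v, c, d = _nni_choices(t, rng)
        _nni_swap(t, v, c, d)
        return t, p, 0.0
    if move_name == "spr":
        n_taxa = t.n_taxa
        t.reroot(n_taxa + int(rng.integers(n_taxa - 2)))
        v = int(rng.integers(t.n_nodes - 1))
        if v >= t.root:
            v += 1
        pa = int(t.parent[v])
        if pa == t.root:
            return t, p, 0.0
        sub = set(t.subtree_nodes(v))
        rowp = t.childmat[pa]
        s = int(rowp[0]) if rowp[1] == v else int(rowp[1])
        targets = [u for u in range(t.n_nodes)
                   if u != t.root and u != pa and u != s and u not in sub]
        if not targets:
            return t, p, 0.0
        _spr_detach_regraft(t, v, targets[int(rng.integers(len(targets)))])
        return t, p, 0.0
    if move_name == "branch_scale":
        v = int(rng.integers(t.n_nodes - 1))
        if v >= t.root:
            v += 1
        m = math.exp(tuning * (rng.random() - 0.5))
        t.lengths[v] *= m
        return t, p, math.log(m)
    if move_name in ("pi_beta_simplex", "er_beta_simplex"):
        x = p.pi if move_name.startswith("pi") else p.er
        prop = _beta_simplex_propose(x, tuning, rng)
        if prop is None:
            return None
        xnew, _, logh = prop
        if move_name.startswith("pi"):
            p.pi = xnew
        else:
            p.er = xnew
        return t, p, logh
    if move_name in ("pi_dirichlet_simplex", "er_dirichlet_simplex"):
        x = p.pi if move_name.startswith("pi") else p.er
        prop = _dirichlet_simplex_propose(x, tuning, rng)
        if prop is None:
            return None
        xnew, logh = prop
        if move_name.startswith("pi"):
            p.pi = xnew
        else:
            p.er = xnew
        return t, p, logh
    if move_name == "shape_scale":
        m = math.exp(tuning * (rng.random() - 0.5))
        p.shape *= m
        return t, p, math.log(m)
    if move_name == "pinv_beta":
        prop = _beta_centred_propose(p.pinv, tuning, rng)
        if prop is None:
            return None
        p.pinv, logh = prop
        return t, p, logh
    raise ValueError(f"unknown move {move_name!r}")
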