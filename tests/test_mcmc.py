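import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats as sps

from phyloppc.mcmc import (
    MCMCConfig,
    apply_move,
    default_move_weights,
    mcmc_run,
    _nni_choices,
    _nni_swap,
)
from phyloppc.simulate import simulate_alignment
from phyloppc.substitution import GTR_GI, JC, PriorSpec, draw_model_params, \
    jc_params
from phyloppc.trees import sample_branch_lengths, sample_topology

from conftest import make_four_taxon_tree


class TestMoves:
    def test_nni_is_involution(self, rng):
        tree = sample_branch_lengths(sample_topology(8, rng), 10.0, rng)
        for _ in range(20):
            key = tree.topology_key()
            v, c, d = _nni_choices(tree, rng)
            _nni_swap(tree, v, c, d)
            assert tree.topology_key() != key  # NNI always changes it
            _nni_swap(tree, v, d, c)
            tree.validate()
            assert tree.topology_key() == key

    def test_nni_changes_topology_once(self, rng):
        tree = sample_branch_lengths(sample_topology(6, rng), 10.0, rng)
        t2, _, logh = apply_move(tree, jc_params(), "nni", 0.0, rng)
        assert logh == 0.0
        from phyloppc.stats import rf_distance

        assert rf_distance(tree, t2) == 2  # one internal edge rearranged

    def test_spr_preserves_length_multiset(self, rng):
        tree = sample_branch_lengths(sample_topology(8, rng), 10.0, rng)
        before = np.sort(np.delete(tree.lengths, tree.root))
        for _ in range(20):
            t2, _, logh = apply_move(tree, jc_params(), "spr", 0.0, rng)
            t2.validate()
            assert logh == 0.0
            after = np.sort(np.delete(t2.lengths, t2.root))
            np.testing.assert_allclose(after, before)

    def test_branch_scale_hastings(self, rng):
        tree = sample_branch_lengths(sample_topology(5, rng), 10.0, rng)
        t2, _, logh = apply_move(tree, jc_params(), "branch_scale", 0.8, rng)
        changed = np.flatnonzero(~np.isclose(
            np.nan_to_num(t2.lengths), np.nan_to_num(tree.lengths)))
        assert changed.size == 1
        v = changed[0]
        assert logh == pytest.approx(
            math.log(t2.lengths[v] / tree.lengths[v]))

    def test_scale_move_detailed_balance_on_exponential(self, rng):
        """A multiplier move with log-Hastings = log(m) has the correct
        Jacobian: a 1-D chain targeting Exponential(1) reproduces it."""
        x = 1.0
        samples = []
        for i in range(40_000):
            m = math.exp(1.5 * (rng.random() - 0.5))
            y = x * m
            logr = -(y - x) + math.log(m)
            if math.log(rng.random()) < logr:
                x = y
            if i % 8 == 0:
                samples.append(x)
        assert sps.kstest(samples, "expon").pvalue > 0.01

    @pytest.mark.parametrize("move", ["pi_beta_simplex",
                                      "pi_dirichlet_simplex",
                                      "er_beta_simplex",
                                      "er_dirichlet_simplex"])
    def test_simplex_moves_stay_on_simplex(self, rng, move):
        spec = PriorSpec(n_taxa=4, model_flavor=GTR_GI)
        params = draw_model_params(spec, rng)
        tree = sample_branch_lengths(sample_topology(4, rng), 10.0, rng)
        for _ in range(50):
            out = apply_move(tree, params, move, 30.0, rng)
            if out is None:
                continue
            _, p2, _ = out
            x = p2.pi if move.startswith("pi") else p2.er
            assert abs(x.sum() - 1.0) < 1e-12
            assert (x > 0).all()

    def test_pinv_move_stays_in_unit_interval(self, rng):
        spec = PriorSpec(n_taxa=4, model_flavor=GTR_GI)
        params = draw_model_params(spec, rng)
        tree = sample_branch_lengths(sample_topology(4, rng), 10.0, rng)
        for _ in range(50):
            out = apply_move(tree, params, "pinv_beta", 10.0, rng)
            if out is not None:
                assert 0.0 < out[1].pinv < 1.0


class TestConfig:
    def test_param_moves_rejected_under_jc(self):
        spec = PriorSpec(n_taxa=4, model_flavor=JC)
        cfg = MCMCConfig(move_weights={"nni": 1.0, "branch_scale": 1.0,
                                       "shape_scale": 1.0})
        with pytest.raises(ValueError, match="not applicable"):
            cfg.resolved_weights(spec)

    def test_topology_move_required(self):
        spec = PriorSpec(n_taxa=4, model_flavor=JC)
        cfg = MCMCConfig(move_weights={"branch_scale": 1.0})
        with pytest.raises(ValueError, match="topology"):
            cfg.resolved_weights(spec)

    def test_default_weights_scale_with_taxa(self):
        w = default_move_weights(PriorSpec(n_taxa=64, model_flavor=JC))
        assert w["nni"] == 64.0
        assert w["spr"] == pytest.approx(6.4)
        assert w["branch_scale"] == 64.0

    def test_default_thin_targets_200_draws(self):
        assert MCMCConfig(sample_iters=10_000).resolved_thin() == 50
        assert MCMCConfig(sample_iters=100).resolved_thin() == 1


class TestSampler:
    def test_empty_trace(self, rng):
        spec = PriorSpec(n_taxa=4, model_flavor=JC)
        cfg = MCMCConfig(burnin_iters=5, sample_iters=0, thin=1)
        trace = mcmc_run(None, spec, cfg, rng)
        assert len(trace) == 0

    def test_seed_determinism(self, rng):
        spec = PriorSpec(n_taxa=6, model_flavor=JC)
        tree = sample_branch_lengths(sample_topology(6, rng), 10.0, rng)
        aln = simulate_alignment(tree, jc_params(), 60, rng)
        cfg = MCMCConfig(burnin_iters=20, sample_iters=100, thin=5)
        tr1 = mcmc_run(aln, spec, cfg, np.random.default_rng(9))
        tr2 = mcmc_run(aln, spec, cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(tr1.log_posteriors, tr2.log_posteriors)
        assert [t.newick() for t in tr1.trees] == \
            [t.newick() for t in tr2.trees]

    def test_prior_recovery_constant_likelihood(self):
        """With a constant likelihood the sampler must reproduce the
        priors: Exponential branch lengths and uniform topologies."""
        spec = PriorSpec(n_taxa=4, model_flavor=JC)
        cfg = MCMCConfig(burnin_iters=200, sample_iters=40_000, thin=8)
        trace = mcmc_run(None, spec, cfg, np.random.default_rng(171))
        bl = np.array([t.lengths[0] for t in trace.trees])
        assert sps.kstest(bl, "expon", args=(0, 0.1)).pvalue > 0.01
        counts = Counter(t.topology_key() for t in trace.trees)
        assert len(counts) == 3
        assert sps.chisquare(list(counts.values())).pvalue > 0.01

    def test_replicates_concatenate(self, rng):
        spec = PriorSpec(n_taxa=4, model_flavor=JC)
        cfg = MCMCConfig(burnin_iters=10, sample_iters=50, thin=5,
                         replicates=2)
        trace = mcmc_run(None, spec, cfg, rng)
        assert len(trace) == 20  # 2 x floor(50 / 5)

    def test_strong_signal_recovers_topology(self, rng):
        """A long internal branch and short terminals at 1,000 sites
        pin the 4-taxon topology: the posterior mode matches the truth
        in at least 19 of 20 replicates."""
        spec = PriorSpec(n_taxa=4, model_flavor=JC)
        true = make_four_taxon_tree(internal=0.5, terminal=0.05,
                                    labels=["t1", "t2", "t3", "t4"])
        true_key = true.topology_key()
        cfg = MCMCConfig(burnin_iters=100, sample_iters=500, thin=5)
        hits = 0
        for rep in range(20):
            crng = np.random.default_rng(1000 + rep)
            aln = simulate_alignment(true, jc_params(), 1000, crng)
            trace = mcmc_run(aln, spec, cfg, crng)
            counts = Counter(t.topology_key() for t in trace.trees)
            if counts.most_common(1)[0][0] == true_key:
                hits += 1
        assert hits >= 19
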