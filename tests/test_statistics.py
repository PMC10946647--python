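import math

import numpy as np
import pytest
from scipy import stats as sps

from phyloppc.mcmc import MCMCConfig, PosteriorTrace, mcmc_run
from phyloppc.simulate import Alignment, simulate_alignment
from phyloppc.stats import (
    DATA_STATISTICS,
    INFERENCE_STATISTICS,
    compute_data_statistics,
    compute_inference_statistics,
    gc_stats,
    invariant_site_stats,
    multinomial_likelihood,
    pairwise_difference_stats,
    rf_distance,
    rf_summary,
    tajimas_d,
    tajimas_pi,
    topology_entropy,
    tree_length_stats,
    watterson_theta,
)
from phyloppc.substitution import JC, PriorSpec, jc_params
from phyloppc.trees import sample_branch_lengths, sample_topology

from conftest import alignment_from_columns
from oracles import ordered_vector_quantile, tajimas_d_reference

def pair_fixture():
    """3 sequences of length 4 with pairwise mismatch counts {1, 2, 3}."""
    return Alignment.from_sequences(
        ["a", "b", "c"], ["AAAA", "CAAA", "CCTA"])


class TestRegistry:
    def test_exactly_eleven_and_nine(self):
        assert len(DATA_STATISTICS) == 11
        assert len(INFERENCE_STATISTICS) == 9
        assert set(compute_data_statistics(
            alignment_from_columns(["ACGT", "ACTT"]))) == set(DATA_STATISTICS)

    def test_fast_path_matches_registry(self, rng):
        tree = sample_branch_lengths(sample_topology(6, rng), 10.0, rng)
        aln = simulate_alignment(tree, jc_params(), 80, rng)
        fast = compute_data_statistics(aln)
        for name, fn in DATA_STATISTICS.items():
            v = fn(aln)
            if math.isnan(v):
                assert math.isnan(fast[name])
            else:
                assert fast[name] == pytest.approx(v)


class TestInvariantSites:
    def test_all_identical_rows(self):
        aln = alignment_from_columns(["AAA"] * 7)
        assert invariant_site_stats(aln) == (7, 7, 0)

    def test_run_structure(self):
        # columns: inv, var, inv, inv, var
        aln = alignment_from_columns(["AAA", "ACA", "GGG", "TTT", "CAA"])
        assert invariant_site_stats(aln) == (3, 2, 1)

    def test_no_invariant_columns(self):
        aln = alignment_from_columns(["ACA", "AGA", "CTA"])
        assert invariant_site_stats(aln) == (0, 0, 3)


class TestPairwiseDifferences:
    def test_identical_sequences(self):
        aln = Alignment.from_sequences(["a", "b"], ["ACGT", "ACGT"])
        assert pairwise_difference_stats(aln) == (0.0, 0.0)

    def test_hand_fixture(self):
        aln = pair_fixture()
        # mismatches: (a,b)=1, (a,c)=3, (b,c)=2 over 4 sites
        assert pairwise_difference_stats(aln) == (0.25, 0.75)
        assert tajimas_pi(aln) == pytest.approx(2.0)

    def test_range_and_row_permutation_invariance(self, rng):
        tree = sample_branch_lengths(sample_topology(5, rng), 10.0, rng)
        aln = simulate_alignment(tree, jc_params(), 50, rng)
        lo, hi = pairwise_difference_stats(aln)
        assert 0.0 <= lo <= hi <= 1.0
        perm = rng.permutation(aln.n_taxa)
        shuffled = Alignment([aln.taxa[i] for i in perm], aln.codes[perm])
        assert pairwise_difference_stats(shuffled) == (lo, hi)
        assert tajimas_pi(shuffled) == pytest.approx(tajimas_pi(aln))

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError):
            pairwise_difference_stats(
                Alignment.from_sequences(["a"], ["ACGT"]))


class TestGC:
    def test_all_g(self):
        aln = Alignment.from_sequences(["a", "b"], ["GGGG", "GGGG"])
        assert gc_stats(aln) == (1.0, 0.0)

    def test_two_sequence_fixture(self):
        aln = Alignment.from_sequences(["a", "b"],
                                       ["GCGCA" + "A" * 5,
                                        "GCGCGC" + "A" * 4])
        mean, var = gc_stats(aln)
        assert mean == pytest.approx(0.5)
        assert var == pytest.approx(0.02)


class TestDiversity:
    def test_watterson_no_variation(self):
        aln = alignment_from_columns(["AA"] * 5)
        assert watterson_theta(aln) == 0.0

    def test_watterson_two_sequences(self):
        aln = Alignment.from_sequences(["a", "b"], ["ACGT", "AAAT"])
        assert watterson_theta(aln) == pytest.approx(2.0)  # a1 = 1

    def test_watterson_four_sequences(self):
        cols = ["ACAA", "AACA", "AAAC", "CAAA", "ACCA", "AACC"] + ["AAAA"]
        aln = alignment_from_columns(cols)
        assert watterson_theta(aln) == pytest.approx(
            6.0 / (1 + 0.5 + 1 / 3))

    def test_tajimas_d_matches_reference_constants(self, rng):
        """Implementation equals an independently coded version built
        from the published constant definitions."""
        for n_taxa in (4, 10):
            tree = sample_branch_lengths(sample_topology(n_taxa, rng),
                                         10.0, rng)
            aln = simulate_alignment(tree, jc_params(), 200, rng)
            s_seg = aln.n_sites - invariant_site_stats(aln)[0]
            if s_seg == 0:
                continue
            want = tajimas_d_reference(n_taxa, s_seg, tajimas_pi(aln))
            assert tajimas_d(aln) == pytest.approx(want, abs=1e-10)

    def test_tajimas_d_sign(self):
        """Excess rare variants (pi < theta_W) push D negative."""
        # 6 singleton segregating sites among 6 sequences
        cols = (["AAAAAC"] + ["AAAAAA"] * 4 + ["CAAAAA"] + ["AAAAAA"] * 4
                + ["ACAAAA"] + ["AAACAA"] + ["AAAACA"] + ["AACAAA"])
        aln = alignment_from_columns(cols)
        assert tajimas_d(aln) < 0

    def test_tajimas_d_undefined_without_segregating_sites(self):
        aln = alignment_from_columns(["AAAA"] * 6)
        assert math.isnan(tajimas_d(aln))


class TestMultinomial:
    def test_single_pattern(self):
        assert multinomial_likelihood(
            alignment_from_columns(["ACG"] * 12)) == pytest.approx(0.0)

    def test_even_split(self):
        aln = alignment_from_columns(["AAA"] * 50 + ["ACA"] * 50)
        assert multinomial_likelihood(aln) == pytest.approx(
            100 * math.log(0.5))

    def test_all_distinct(self):
        cols = ["AAA", "ACA", "AGA", "ATA", "CAA"]
        aln = alignment_from_columns(cols)
        assert multinomial_likelihood(aln) == pytest.approx(
            5 * math.log(1 / 5))


def trace_of(trees):
    return PosteriorTrace(taxa=list(trees[0].taxa), trees=list(trees),
                          params=[jc_params()] * len(trees),
                          log_posteriors=np.zeros(len(trees)),
                          iterations=np.arange(len(trees)),
                          acceptance={})


class TestInferenceStatistics:
    def test_rf_summary_degenerate(self, rng):
        t = sample_branch_lengths(sample_topology(6, rng), 10.0, rng)
        out = rf_summary(trace_of([t.copy() for _ in range(10)]))
        assert out == (0.0,) * 6

    def test_rf_summary_matches_sorted_vector_oracle(self, rng):
        """Alternating two topologies at RF 2: quantiles equal the
        brute-force ordered-vector rule on all pairs."""
        labels = [f"t{i + 1}" for i in range(6)]
        t1 = sample_branch_lengths(sample_topology(6, rng, labels),
                                   10.0, rng)
        while True:
            t2 = sample_branch_lengths(sample_topology(6, rng, labels),
                                       10.0, rng)
            if rf_distance(t1, t2) == 2:
                break
        trees = [t1 if i % 2 == 0 else t2 for i in range(12)]
        got = rf_summary(trace_of(trees))
        dists = [rf_distance(trees[i], trees[j])
                 for i in range(12) for j in range(i + 1, 12)]
        want = tuple([np.mean(dists)] + [
            ordered_vector_quantile(dists, q)
            for q in (0.25, 0.5, 0.75, 0.99, 0.999)])
        assert got == pytest.approx(want)

    def test_rf_mean_order_invariant(self, rng):
        labels = [f"t{i + 1}" for i in range(5)]
        trees = [sample_branch_lengths(sample_topology(5, rng, labels),
                                       10.0, rng) for _ in range(8)]
        m1 = rf_summary(trace_of(trees))[0]
        m2 = rf_summary(trace_of(trees[::-1]))[0]
        assert m1 == pytest.approx(m2)

    def test_entropy_point_mass(self, rng):
        t = sample_branch_lengths(sample_topology(6, rng), 10.0, rng)
        tr = trace_of([t.copy() for _ in range(5)])
        assert topology_entropy(tr) == pytest.approx(
            math.log(105))  # (2*6-5)!! = 105

    def test_entropy_all_unique(self, rng):
        """Every sampled topology unique: the statistic collapses to
        ln((2n-5)!!) - ln(m) whatever the trees are."""
        labels = [f"t{i + 1}" for i in range(8)]
        seen, trees = set(), []
        while len(trees) < 6:
            t = sample_branch_lengths(sample_topology(8, rng, labels),
                                      10.0, rng)
            if t.topology_key() not in seen:
                seen.add(t.topology_key())
                trees.append(t)
        want = sum(math.log(k) for k in range(3, 12, 2)) - math.log(6)
        assert topology_entropy(trace_of(trees)) == pytest.approx(want)

    def test_entropy_even_split(self, rng):
        labels = [f"t{i + 1}" for i in range(6)]
        t1 = sample_branch_lengths(sample_topology(6, rng, labels),
                                   10.0, rng)
        while True:
            t2 = sample_branch_lengths(sample_topology(6, rng, labels),
                                       10.0, rng)
            if t2.topology_key() != t1.topology_key():
                break
        tr = trace_of([t1, t2] * 4)
        assert topology_entropy(tr) == pytest.approx(
            math.log(105) - math.log(2))

    def test_tree_length_stats(self, rng):
        t1 = sample_branch_lengths(sample_topology(4, rng), 10.0, rng)
        t2 = t1.copy()
        t1.lengths[np.arange(t1.n_nodes) != t1.root] = 0.2  # TL = 1.0
        t2.lengths[np.arange(t2.n_nodes) != t2.root] = 0.4  # TL = 2.0
        mean, var = tree_length_stats(trace_of([t1, t2]))
        assert (mean, var) == (pytest.approx(1.5), pytest.approx(0.5))

    def test_prior_trace_mean_tree_length(self):
        """Prior-only posterior: mean tree length approaches
        (2n-3)/bl_rate (sum of Exponential means)."""
        spec = PriorSpec(n_taxa=5, model_flavor=JC)
        cfg = MCMCConfig(burnin_iters=100, sample_iters=20_000, thin=10)
        tr = mcmc_run(None, spec, cfg, np.random.default_rng(77))
        mean_tl, _ = tree_length_stats(tr)
        assert mean_tl == pytest.approx(7 / 10, rel=0.1)
        stats = compute_inference_statistics(tr)
        assert set(stats) == set(INFERENCE_STATISTICS)


class TestColumnOrderInvariance:
    def test_unordered_statistics_ignore_column_order(self, rng):
        """All data-based statistics except the block lengths are
        column-order invariant; the block statistics respond only to
        adjacency."""
        tree = sample_branch_lengths(sample_topology(5, rng), 10.0, rng)
        aln = simulate_alignment(tree, jc_params(), 60, rng)
        perm = rng.permutation(aln.n_sites)
        shuffled = Alignment(list(aln.taxa), aln.codes[:, perm])
        a = compute_data_statistics(aln)
        b = compute_data_statistics(shuffled)
        for name in DATA_STATISTICS:
            if name in ("max_invariant_block", "max_variable_block"):
                continue
            if math.isnan(a[name]):
                assert math.isnan(b[name])
            else:
                assert b[name] == pytest.approx(a[name])


class TestAncillarity:
    def test_gc_statistics_independent_of_tree_under_jc(self):
        """Mean and variance of GC content have the same sampling
        distribution across two different random trees drawn from the
        branch-length prior regime (JC symmetry)."""
        rng = np.random.default_rng(55)
        t1 = sample_branch_lengths(sample_topology(8, rng), 10.0, rng)
        t2 = sample_branch_lengths(sample_topology(8, rng), 10.0, rng)
        m1, v1, m2, v2 = [], [], [], []
        for _ in range(300):
            a1 = simulate_alignment(t1, jc_params(), 100, rng)
            a2 = simulate_alignment(t2, jc_params(), 100, rng)
            g1, g2 = gc_stats(a1), gc_stats(a2)
            m1.append(g1[0]); v1.append(g1[1])
            m2.append(g2[0]); v2.append(g2[1])
        assert sps.ks_2samp(m1, m2).pvalue > 0.01
        assert sps.ks_2samp(v1, v2).pvalue > 0.01
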