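import itertools

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import mutual_info_score

from dysbionet import (
    build_network,
    candidate_edges,
    fragmentation,
    gatekeeper_test,
    hub_ranking,
    merge_pvalues,
    pair_score,
    reboot_pvalue,
    to_relative,
)
from dysbionet.network import _double_edge_swaps, _mi_matrix, _score_matrix
from dysbionet.simulate import (
    SynthSpec,
    correlation_benchmark_spec,
    generate_samples,
    make_graph_fixture,
)
from conftest import random_profile


class TestPairScores:
    def test_identical_vectors(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert pair_score(x, x, "pearson") == pytest.approx(1.0)
        assert pair_score(x, x, "spearman") == pytest.approx(1.0)
        assert pair_score(x, x, "bray_curtis") == pytest.approx(0.0)
        assert pair_score(x, x, "kld") == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports(self):
        x = np.array([1.0, 2.0, 0.0, 0.0])
        y = np.array([0.0, 0.0, 3.0, 1.0])
        assert pair_score(x, y, "bray_curtis") == pytest.approx(1.0)

    def test_constant_vector_undefined_for_correlations(self):
        x = np.full(6, 2.0)
        y = np.arange(6, dtype=float)
        assert np.isnan(pair_score(x, y, "pearson"))
        assert np.isnan(pair_score(x, y, "spearman"))

    def test_kld_symmetric_nonnegative(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(10), rng.random(10)
        k = pair_score(x, y, "kld")
        assert k >= 0
        assert k == pytest.approx(pair_score(y, x, "kld"))

    def test_mi_tracks_dependence(self):
        rng = np.random.default_rng(1)
        x = rng.random(100)
        assert pair_score(x, x + rng.normal(0, 0.01, 100), "mutual_information") > \
            pair_score(x, rng.random(100), "mutual_information")

    def test_mi_matches_sklearn_on_bins(self):
        """Oracle: MI of the rank-binned variables computed by sklearn."""
        rng = np.random.default_rng(2)
        data = rng.random((5, 40))
        mi = _mi_matrix(data, nbins=4)
        n = data.shape[1]
        for i, j in itertools.combinations(range(5), 2):
            order_i = np.argsort(np.argsort(data[i], kind="stable"))
            order_j = np.argsort(np.argsort(data[j], kind="stable"))
            bins_i = order_i * 4 // n
            bins_j = order_j * 4 // n
            assert mi[i, j] == pytest.approx(mutual_info_score(bins_i, bins_j), abs=1e-12)


class TestCandidateEdges:
    def test_clamp_with_warning(self):
        p = random_profile(10, 3, seed=0)
        with pytest.warns(UserWarning, match="pairs available"):
            edges = candidate_edges(p, "pearson", top_n=1000)
        assert len(edges) == 3

    def test_planted_pair_in_positive_candidates(self):
        spec = correlation_benchmark_spec(seed=0, n_pairs=3)
        t, truth = generate_samples(spec)
        prof = to_relative(t)
        edges = candidate_edges(prof, "pearson", top_n=100)
        pos = {tuple(sorted((a, b))) for a, b, s in
               zip(edges.otu_a, edges.otu_b, edges.sign) if s > 0}
        planted = {tuple(sorted((a, b))) for a, b, _ in truth.correlated_pairs}
        assert planted & pos

    def test_bray_copresence_sign_positive(self):
        p = random_profile(10, 5, seed=1)
        edges = candidate_edges(p, "bray_curtis", top_n=2)
        smallest = edges.nsmallest(1, "score")
        assert int(smallest.sign.iloc[0]) == 1


class TestRebootAndMerge:
    def test_reboot_deterministic(self):
        p = random_profile(20, 8, seed=2)
        a = reboot_pvalue(("o0", "o1"), "spearman", p, n_perm=200, seed=5)
        b = reboot_pvalue(("o0", "o1"), "spearman", p, n_perm=200, seed=5)
        assert a == b

    def test_planted_pair_significant(self):
        hits = 0
        for seed in range(5):
            spec = correlation_benchmark_spec(seed=seed, n_pairs=1)
            t, truth = generate_samples(spec)
            prof = to_relative(t)
            a, b, _ = truth.correlated_pairs[0]
            hits += reboot_pvalue((a, b), "spearman", prof, n_perm=200, seed=seed) <= 0.05
        assert hits >= 4

    def test_low_n_perm_warns(self):
        p = random_profile(12, 4, seed=3)
        with pytest.warns(UserWarning, match="unstable"):
            reboot_pvalue(("o0", "o1"), "pearson", p, n_perm=50, seed=0)

    def test_merge_single_p_identity(self):
        assert merge_pvalues([0.2], "fisher") == pytest.approx(0.2)
        assert merge_pvalues([0.2], "brown", null_pvalues=np.ones((10, 1))) == pytest.approx(0.2)

    def test_brown_absorbs_perfect_dependence(self):
        rng = np.random.default_rng(0)
        null = np.repeat(rng.random((5000, 1)), 4, axis=1)
        for p in (0.03, 0.2, 0.6):
            merged = merge_pvalues([p] * 4, "brown", null_pvalues=null)
            assert merged == pytest.approx(p, abs=0.02)
        # Fisher, by contrast, overstates small shared evidence
        assert merge_pvalues([0.03] * 4, "fisher") < 0.01

    def test_fisher_uniform_under_independence(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(1)
        merged = [merge_pvalues(rng.random(4), "fisher") for _ in range(500)]
        assert kstest(merged, "uniform").pvalue > 0.01

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            merge_pvalues([], "fisher")


# merged permutation p-values bottom out near 1/(n_perm+1); surviving a
# BH pass over ~5000 candidate pairs therefore needs n_perm ~ 1000
@pytest.fixture(scope="module")
def planted_net():
    spec = correlation_benchmark_spec(seed=7, n_pairs=10)
    t, truth = generate_samples(spec)
    net = build_network(t, n_perm=1000, seed=8)
    return t, truth, net


class TestBuildNetwork:
    def test_simple_graph_invariants(self, planted_net):
        _, _, net = planted_net
        g = net.graph()
        assert not any(a == b for a, b in g.edges)
        pairs = [tuple(sorted((a, b))) for a, b in zip(net.edges.otu_a, net.edges.otu_b)]
        assert len(pairs) == len(set(pairs))
        assert (net.edges.support >= 2).all()
        assert (net.edges.q <= 0.05).all()

    def test_recovers_planted_pairs(self, planted_net):
        _, truth, net = planted_net
        found = {tuple(sorted((a, b))) for a, b in zip(net.edges.otu_a, net.edges.otu_b)}
        planted = {tuple(sorted((a, b))) for a, b, _ in truth.correlated_pairs}
        assert len(found & planted) / len(planted) >= 0.7

    def test_invariant_to_sample_and_otu_order(self):
        spec = SynthSpec(
            n_otus=40, depth=50_000, n_per_cohort=30, log_noise_sd=1.0,
            correlated_pairs=tuple(
                (f"OTU{2 * k + 1:04d}", f"OTU{2 * k + 2:04d}", 0.9) for k in range(5)),
            seed=3,
        )
        t, _ = generate_samples(spec)
        rng = np.random.default_rng(0)
        rows = rng.permutation(t.n_samples)
        cols = rng.permutation(t.n_otus)
        from dysbionet import OtuTable

        shuffled = OtuTable([t.sample_ids[i] for i in rows],
                            [t.otu_ids[j] for j in cols],
                            t.counts[np.ix_(rows, cols)])
        net1 = build_network(t, n_perm=800, seed=5)
        net2 = build_network(shuffled, n_perm=800, seed=5)
        e1 = {tuple(sorted((a, b))) for a, b in zip(net1.edges.otu_a, net1.edges.otu_b)}
        e2 = {tuple(sorted((a, b))) for a, b in zip(net2.edges.otu_a, net2.edges.otu_b)}
        # permutation-stream differences aside, the retained edge sets agree
        overlap = len(e1 & e2) / max(1, len(e1 | e2))
        assert overlap >= 0.8

    def test_small_sample_guard(self):
        from conftest import random_table

        with pytest.raises(ValueError, match="5 samples"):
            build_network(random_table(4, 10, seed=0))


class TestHubRanking:
    def test_star_center_first(self):
        g = nx.star_graph(9)  # center 0
        ranked = hub_ranking(g, top_n=3)
        assert ranked.otu_id.iloc[0] == 0
        assert ranked.degree.iloc[0] == 9

    def test_complete_graph_tie_by_id(self):
        g = nx.relabel_nodes(nx.complete_graph(4), {0: "d", 1: "c", 2: "b", 3: "a"})
        ranked = hub_ranking(g, top_n=4)
        assert list(ranked.otu_id) == ["a", "b", "c", "d"]

    def test_relabel_consistency(self):
        g = nx.gnp_random_graph(12, 0.3, seed=1)
        mapping = {i: f"n{i:02d}" for i in g.nodes}
        r1 = hub_ranking(g, top_n=5)
        r2 = hub_ranking(nx.relabel_nodes(g, mapping), top_n=5)
        assert [mapping[i] for i in r1.otu_id] == list(r2.otu_id)


def brute_force_fragmentation(g: nx.Graph) -> float:
    """Oracle: fraction of ordered node pairs not mutually reachable."""
    nodes = list(g.nodes)
    n = len(nodes)
    unreachable = 0
    for a, b in itertools.permutations(nodes, 2):
        if not nx.has_path(g, a, b):
            unreachable += 1
    return unreachable / (n * (n - 1))


class TestFragmentation:
    def test_closed_forms(self):
        assert fragmentation(nx.path_graph(6)) == 0.0
        assert fragmentation(nx.empty_graph(5)) == 1.0
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        assert fragmentation(g) == pytest.approx(1 - 40 / 90)

    def test_too_small(self):
        with pytest.raises(ValueError):
            fragmentation(nx.empty_graph(1))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_reachability_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        g = nx.gnp_random_graph(n, float(rng.uniform(0, 0.5)), seed=seed)
        assert fragmentation(g) == pytest.approx(brute_force_fragmentation(g))


class TestRewiring:
    def test_degree_sequence_preserved(self):
        g = nx.gnp_random_graph(15, 0.3, seed=3)
        edges = np.array(g.edges)
        rng = np.random.default_rng(0)
        for _ in range(20):
            rewired = _double_edge_swaps(edges, n_swaps=10 * len(edges), rng=rng)
            deg = np.zeros(15, dtype=int)
            for a, b in rewired:
                deg[a] += 1
                deg[b] += 1
            expected = np.array([d for _, d in sorted(g.degree)])
            np.testing.assert_array_equal(deg, expected)
            # simple graph: no duplicates, no self-loops
            pairs = {tuple(sorted(e)) for e in rewired}
            assert len(pairs) == len(rewired)
            assert all(a != b for a, b in rewired)

    def test_clique_cannot_rewire(self):
        g = nx.complete_graph(6)
        edges = np.array(g.edges)
        rewired = _double_edge_swaps(edges, n_swaps=100, rng=np.random.default_rng(0))
        assert {tuple(sorted(e)) for e in rewired} == {tuple(sorted(e)) for e in g.edges}


class TestGatekeeper:
    def test_barbell_bridge_detected(self):
        g, truth = make_graph_fixture("barbell", m=5)
        (bridge,) = truth.bridge_nodes
        res = gatekeeper_test(g, bridge, n_null=2000, seed=0)
        assert res.f_after == pytest.approx(1 - 40 / 90, abs=1e-12)
        assert res.p <= 0.05 and res.significant
        # bridge removal fragments more than any other node's removal
        others = [gatekeeper_test(g, v, n_null=10, seed=1).delta_f
                  for v in g.nodes if v != bridge]
        assert res.delta_f > max(others)

    def test_complete_graph_never_significant(self):
        g = nx.complete_graph(7)
        res = gatekeeper_test(g, 0, n_null=500, seed=2)
        assert res.f_after == 0.0
        assert res.p > 0.9

    def test_deterministic(self):
        g, truth = make_graph_fixture("planted_bridge", n=6, p=0.6, seed=1)
        r1 = gatekeeper_test(g, truth.bridge_nodes[0], n_null=300, seed=9)
        r2 = gatekeeper_test(g, truth.bridge_nodes[0], n_null=300, seed=9)
        assert r1.null_count == r2.null_count and r1.p == r2.p

    def test_absent_node_rejected(self):
        g = nx.path_graph(5)
        with pytest.raises(KeyError):
            gatekeeper_test(g, 99, n_null=10, seed=0)
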