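import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy.stats import norm

from pignon.annotations import AnnotationCatalog
from pignon.clustering import (
    NullModel,
    all_pairs_distances,
    build_null_model,
    clustering_pvalue,
    sample_index_sets,
    sample_tpds,
    score_terms,
    tpd,
)
from tests.conftest import bellman_ford_oracle, random_connected_weighted_graph


class TestAllPairsDistances:
    def test_unit_triangle(self, triangle):
        dist = all_pairs_distances(triangle)
        i = dist.index
        for a, b in itertools.combinations("ABC", 2):
            assert dist.d[i[a], i[b]] == 1.0
        assert np.all(np.diag(dist.d) == 0)

    def test_path_distance_sums_weights(self, weighted_path):
        dist = all_pairs_distances(weighted_path)
        assert dist.d[dist.index["A"], dist.index["C"]] == pytest.approx(0.75)

    def test_matches_bellman_ford_oracle_on_random_graph(self, rng):
        g = random_connected_weighted_graph(30, rng)
        oracle_index, oracle_d = bellman_ford_oracle(g)
        dist = all_pairs_distances(g)
        order = [oracle_index[v] for v in dist.index]
        np.testing.assert_allclose(dist.d, oracle_d[np.ix_(order, order)],
                                   rtol=0, atol=1e-9)

    def test_floyd_warshall_method_agrees(self, rng):
        g = random_connected_weighted_graph(25, rng)
        d1 = all_pairs_distances(g, method="dijkstra")
        d2 = all_pairs_distances(g, method="floyd-warshall")
        np.testing.assert_allclose(d1.d, d2.d, atol=1e-12)

    def test_disconnected_graph_rejected(self):
        g = nx.Graph([("A", "B"), ("C", "D")])
        with pytest.raises(ValueError, match="connected"):
            all_pairs_distances(g)

    def test_symmetry_and_triangle_inequality(self, rng):
        g = random_connected_weighted_graph(15, rng)
        d = all_pairs_distances(g).d
        np.testing.assert_allclose(d, d.T, atol=0)
        n = d.shape[0]
        for i, j, k in itertools.permutations(range(n), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


class TestTPD:
    def test_pair_is_single_distance(self, weighted_path):
        dist = all_pairs_distances(weighted_path)
        assert tpd(dist, {"A", "C"}) == pytest.approx(0.75)

    def test_unit_triangle_is_three(self, triangle):
        dist = all_pairs_distances(triangle)
        assert tpd(dist, {"A", "B", "C"}) == pytest.approx(3.0)

    @pytest.mark.parametrize("n", [4, 6, 9])
    def test_complete_graph_closed_form(self, n):
        g = nx.complete_graph(n)
        nx.set_edge_attributes(g, 1.0, "weight")
        dist = all_pairs_distances(g)
        assert tpd(dist, set(g.nodes)) == pytest.approx(n * (n - 1) / 2)

    def test_hop_count_tpd_is_integer(self, rng):
        g = random_connected_weighted_graph(20, rng)
        nx.set_edge_attributes(g, 1.0, "weight")
        dist = all_pairs_distances(g)
        nodes = list(g.nodes)[:8]
        assert tpd(dist, nodes) == int(tpd(dist, nodes))

    def test_fewer_than_two_proteins_rejected(self, triangle):
        dist = all_pairs_distances(triangle)
        with pytest.raises(ValueError):
            tpd(dist, {"A"})


class TestNullModel:
    def test_degenerate_full_set_sample(self, five_node_graph, rng):
        dist = all_pairs_distances(five_node_graph)
        eligible = sorted(five_node_graph.nodes)
        null = build_null_model(dist, eligible, [5], 100, rng)
        mu, sigma = null.get(5)
        assert sigma == 0.0
        assert mu == pytest.approx(tpd(dist, eligible))

    def test_uniform_sampling_matches_exhaustive_enumeration(self, five_node_graph, rng):
        dist = all_pairs_distances(five_node_graph)
        eligible = sorted(five_node_graph.nodes)
        exact = [tpd(dist, c) for c in itertools.combinations(eligible, 3)]
        exact_mu = float(np.mean(exact))
        n = 20_000
        null = build_null_model(dist, eligible, [3], n, rng)
        mu, sigma = null.get(3)
        se = sigma / math.sqrt(n)
        assert abs(mu - exact_mu) < 3 * se
        assert sigma == pytest.approx(float(np.std(exact, ddof=0)), rel=0.05)

    def test_mean_tpd_increases_with_set_size(self, rng):
        g = random_connected_weighted_graph(30, rng)
        dist = all_pairs_distances(g)
        eligible = sorted(g.nodes)
        null = build_null_model(dist, eligible, [3, 5, 8, 12], 3000, rng)
        mus = [null.get(s)[0] for s in (3, 5, 8, 12)]
        assert mus == sorted(mus)

    def test_weighted_sampling_membership_matches_sequential_oracle(self, rng):
        # counts (10,1,1,1,1): P(member of a size-2 draw) has a closed form
        # under sequential weighted sampling without replacement
        w = np.array([10.0, 1.0, 1.0, 1.0, 1.0])
        W = w.sum()
        analytic = np.array([
            w[v] / W + sum(w[u] / W * w[v] / (W - w[u]) for u in range(5) if u != v)
            for v in range(5)
        ])
        n = 100_000
        picks = sample_index_sets(n, 5, 2, rng, w=w)
        freq = np.bincount(picks.ravel(), minlength=5) / n
        se = np.sqrt(analytic * (1 - analytic) / n)
        assert np.all(np.abs(freq - analytic) < 4 * se)

    def test_first_draw_probability_proportional_to_weight(self, rng):
        # the smallest exponential key is the first sequential draw:
        # P(heavy first) = 10/14
        w = np.array([10.0, 1.0, 1.0, 1.0, 1.0])
        n = 100_000
        keys = rng.exponential(size=(n, 5)) / w
        first = keys.argmin(axis=1)
        p = 10.0 / 14.0
        assert abs(np.mean(first == 0) - p) < 4 * math.sqrt(p * (1 - p) / n)

    def test_oversized_sample_rejected(self, five_node_graph, rng):
        dist = all_pairs_distances(five_node_graph)
        with pytest.raises(ValueError):
            sample_tpds(dist, sorted(five_node_graph.nodes), 6, 10, rng)

    def test_too_few_samples_rejected(self, five_node_graph, rng):
        dist = all_pairs_distances(five_node_graph)
        with pytest.raises(ValueError):
            build_null_model(dist, sorted(five_node_graph.nodes), [3], 1, rng)

    def test_fixed_seed_bit_identical(self, five_node_graph):
        dist = all_pairs_distances(five_node_graph)
        eligible = sorted(five_node_graph.nodes)
        a = build_null_model(dist, eligible, [3, 4], 500, np.random.default_rng(3))
        b = build_null_model(dist, eligible, [3, 4], 500, np.random.default_rng(3))
        assert a.entries == b.entries

    def test_tsv_round_trip(self, five_node_graph, rng, tmp_path):
        dist = all_pairs_distances(five_node_graph)
        null = build_null_model(dist, sorted(five_node_graph.nodes), [3, 4], 100, rng)
        path = tmp_path / "null.tsv"
        null.to_tsv(path)
        loaded = NullModel.from_tsv(path)
        assert loaded.entries == null.entries
        assert loaded.mode == null.mode


class TestClusteringPvalue:
    def test_observation_at_mean_is_half(self):
        assert clustering_pvalue(10.0, 10.0, 2.0) == pytest.approx(0.5)

    def test_standard_normal_quantile(self):
        assert clustering_pvalue(10.0 - 1.959964 * 2.0, 10.0, 2.0) == pytest.approx(
            0.025, abs=1e-6
        )

    def test_degenerate_sigma_conventions(self):
        assert clustering_pvalue(5.0, 4.0, 0.0) == 1.0
        assert clustering_pvalue(4.0, 4.0, 0.0) == 1.0
        assert 0 < clustering_pvalue(3.0, 4.0, 0.0) < 1e-300

    def test_monotone_in_observed_tpd(self, rng):
        ts = np.sort(rng.normal(0, 5, size=50))
        ps = [clustering_pvalue(t, 0.0, 5.0) for t in ts]
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_extreme_observation_stays_in_open_interval(self):
        assert 0 < clustering_pvalue(-1e6, 0.0, 1.0) < 1
        assert 0 < clustering_pvalue(1e6, 0.0, 1.0) <= 1


class TestScoreTerms:
    def test_identical_protein_sets_identical_scores(self, five_node_graph, rng):
        dist = all_pairs_distances(five_node_graph)
        eligible = sorted(five_node_graph.nodes)
        null = build_null_model(dist, eligible, [3], 2000, rng)
        cat = AnnotationCatalog(terms={"T1": {"A", "B", "C"}, "T2": {"A", "B", "C"}})
        s1, s2 = score_terms(dist, cat, null)
        assert (s1.tpd, s1.p_value) == (s2.tpd, s2.p_value)

    def test_closest_triple_achieves_minimum_tpd(self, rng):
        g = random_connected_weighted_graph(20, rng)
        dist = all_pairs_distances(g)
        triples = list(itertools.combinations(sorted(g.nodes), 3))
        tpds = [tpd(dist, t) for t in triples]
        best = set(triples[int(np.argmin(tpds))])
        null = build_null_model(dist, sorted(g.nodes), [3], 2000, rng)
        cat = AnnotationCatalog(
            terms={"BEST": best, **{f"R{i}": set(t) for i, t in enumerate(triples[:20])}}
        )
        scores = {s.term: s for s in score_terms(dist, cat, null)}
        assert scores["BEST"].tpd == pytest.approx(min(tpds))
        assert all(scores["BEST"].p_value <= s.p_value for s in scores.values())

    def test_planted_tight_module_beats_random_sets(self, rng):
        # low-weight clique embedded in a unit-weight background graph
        g = random_connected_weighted_graph(30, rng)
        nx.set_edge_attributes(g, 1.0, "weight")
        module = sorted(g.nodes)[:5]
        for u, v in itertools.combinations(module, 2):
            g.add_edge(u, v, weight=0.1)
        dist = all_pairs_distances(g)
        null = build_null_model(dist, sorted(g.nodes), [5], 5000, rng)
        random_sets = {
            f"R{i}": set(rng.choice(sorted(g.nodes), size=5, replace=False))
            for i in range(21)
        }
        cat = AnnotationCatalog(terms={"MOD": set(module), **random_sets})
        scores = {s.term: s.p_value for s in score_terms(dist, cat, null)}
        median_random = np.median([scores[t] for t in random_sets])
        assert scores["MOD"] < median_random

    def test_uncovered_size_names_term(self, five_node_graph, rng):
        dist = all_pairs_distances(five_node_graph)
        null = build_null_model(dist, sorted(five_node_graph.nodes), [3], 100, rng)
        cat = AnnotationCatalog(terms={"BIG": {"A", "B", "C", "D"}})
        with pytest.raises(KeyError, match="BIG"):
            score_terms(dist, cat, null)

    def test_effective_set_restricted_to_network(self, five_node_graph, rng):
        dist = all_pairs_distances(five_node_graph)
        null = build_null_model(dist, sorted(five_node_graph.nodes), [3], 100, rng)
        cat = AnnotationCatalog(terms={"T": {"A", "B", "C", "ZZ_NOT_IN_NET"}})
        (score,) = score_terms(dist, cat, null)
        assert score.size == 3
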