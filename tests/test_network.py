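import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import rhizofun as rf
from rhizofun.network import ConstantVectorError, NetworkParams, TopologyRecord
from rhizofun.tables import AsvTable

from conftest import random_asv_table
from oracles import NaiveGraph, naive_bh, naive_network_edges


def _table(counts_dict, kingdom="bacteria", samples=None):
    df = pd.DataFrame(counts_dict).T
    if samples is not None:
        df.columns = samples
    else:
        df.columns = [f"s{j}" for j in range(df.shape[1])]
    return AsvTable(counts=df.astype(int), kingdom=kingdom)


class TestFilterCoreAsvs:
    def test_threshold_at_half_percent(self):
        # A at 0.6% and B at 0.4% of every sample total (1000)
        counts = {"A": [6] * 4, "B": [4] * 4, "C": [990] * 4}
        table = _table(counts)
        kept = rf.filter_core_asvs(table)
        assert kept.asv_ids == ["A", "C"]

    def test_single_asv_is_always_core(self):
        table = _table({"A": [10, 20, 30]})
        assert rf.filter_core_asvs(table).asv_ids == ["A"]

    def test_matches_bruteforce_mean_relative_abundance(self):
        table = random_asv_table(np.random.default_rng(0), n_asvs=300, depth=3000)
        kept = set(rf.filter_core_asvs(table).asv_ids)
        expected = set()
        for asv in table.asv_ids:
            rels = [table.counts.at[asv, s] / table.counts[s].sum()
                    for s in table.sample_ids]
            if np.mean(rels) > 0.005:
                expected.add(asv)
        assert kept == expected


class TestSpearmanEdgeTest:
    def test_monotone_profiles(self):
        r, p = rf.spearman_edge_test([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert r == 1.0 and p == np.finfo(float).tiny
        r, _ = rf.spearman_edge_test([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert r == -1.0

    def test_rank_difference_formula_example(self):
        # sum d^2 = 4 -> rho = 1 - 6*4/(5*24) = 0.8
        r, p = rf.spearman_edge_test([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        np.testing.assert_allclose(r, 0.8, atol=1e-12)
        assert 0 < p < 1

    def test_constant_vector_raises(self):
        with pytest.raises(ConstantVectorError):
            rf.spearman_edge_test([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            rf.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04],
            atol=1e-14)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(rf.bh_adjust([0.37]), [0.37])

    def test_matches_stepup_oracle_on_uniforms(self):
        rng = np.random.default_rng(6)
        p = rng.random(1000)
        np.testing.assert_allclose(rf.bh_adjust(p), naive_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rf.bh_adjust([0.5, 1.5])


class TestBuildNetwork:
    def test_identical_rank_order_yields_one_positive_edge(self):
        rng = np.random.default_rng(0)
        base = np.sort(rng.integers(10, 100, size=10))
        table = _table({"A": base, "B": base * 2 + 1})
        g = rf.build_network(table)
        assert g.number_of_edges() == 1
        assert g.edges["A", "B"]["sign"] == "+"
        assert g.edges["A", "B"]["r"] == 1.0

    def test_default_thresholds(self):
        params = NetworkParams()
        assert params.r_threshold == 0.70
        assert params.p_threshold == 0.01
        assert params.min_mean_rel_abund == 0.005
        assert params.p_adjust == "bh"

    def test_too_few_samples_rejected(self):
        table = _table({"A": [1, 2, 3, 4], "B": [4, 3, 2, 1]})
        with pytest.raises(ValueError, match="underpowered"):
            rf.build_network(table)

    def test_edge_set_matches_bruteforce_oracle(self):
        table = random_asv_table(np.random.default_rng(12), n_asvs=8,
                                 n_samples=12, depth=300)
        g = rf.build_network(table, NetworkParams(min_mean_rel_abund=0.0,
                                                  r_threshold=0.3,
                                                  p_threshold=0.2))
        counts = {a: table.counts.loc[a].tolist() for a in table.asv_ids}
        expected = naive_network_edges(counts, r_threshold=0.3, p_threshold=0.2)
        got = {frozenset(e) for e in g.edges}
        assert got == set(expected)
        for pair, r in expected.items():
            u, v = tuple(pair)
            np.testing.assert_allclose(g.edges[u, v]["r"], r, atol=1e-10)

    def test_table_order_does_not_matter(self):
        rng = np.random.default_rng(3)
        bact = random_asv_table(rng, n_asvs=10, n_samples=10, kingdom="bacteria")
        fung = random_asv_table(rng, n_asvs=6, n_samples=10, kingdom="fungi",
                                depth=800)
        params = NetworkParams(min_mean_rel_abund=0.0, r_threshold=0.4,
                               p_threshold=0.3)
        g1 = rf.build_network([bact, fung], params)
        g2 = rf.build_network([fung, bact], params)
        assert {frozenset(e) for e in g1.edges} == {frozenset(e) for e in g2.edges}
        assert not any(u == v for u, v in g1.edges)

    def test_positive_only_drops_negative_correlations(self):
        up = list(range(10, 20))
        table = _table({"A": up, "B": up[::-1], "C": [u + 1 for u in up]})
        g = rf.build_network(table, NetworkParams(positive_only=True))
        signs = {d["sign"] for _, _, d in g.edges(data=True)}
        assert signs <= {"+"}
        assert frozenset(("A", "B")) not in {frozenset(e) for e in g.edges}


class TestTopology:
    def test_complete_graph_k4(self):
        rec = rf.topology(nx.complete_graph(4), "k4")
        assert (rec.n_nodes, rec.n_edges, rec.avg_degree) == (4, 6, 3)
        assert rec.density == 1.0 and rec.clustering_coef == 1.0
        assert rec.avg_path_length == 1.0

    def test_path_graph_p4(self):
        rec = rf.topology(nx.path_graph(4), "p4")
        np.testing.assert_allclose(rec.avg_degree, 1.5)
        np.testing.assert_allclose(rec.density, 0.5)
        assert rec.clustering_coef == 0.0
        np.testing.assert_allclose(rec.avg_path_length, 10 / 6)

    def test_star_graph_betweenness(self):
        rec = rf.topology(nx.star_graph(3), "star")
        # hub normalized betweenness 1.0, three leaves 0 -> mean 0.25
        np.testing.assert_allclose(rec.mean_betweenness, 0.25)

    def test_empty_graph_flagged(self):
        rec = rf.topology(nx.Graph(), "empty")
        assert rec.is_empty
        assert rec.n_nodes == rec.n_edges == 0
        assert rec.avg_degree == rec.density == rec.avg_path_length == 0.0

    def test_disconnected_graph_averages_connected_pairs_only(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        rec = rf.topology(g, "two-edges")
        np.testing.assert_allclose(rec.avg_path_length, 1.0)

    def test_matches_bruteforce_on_random_graphs(self):
        for seed in range(5):
            g = nx.gnp_random_graph(9, 0.35, seed=seed)
            rec = rf.topology(g, str(seed))
            naive = NaiveGraph(g.nodes, g.edges)
            np.testing.assert_allclose(rec.avg_degree, naive.avg_degree(), atol=1e-10)
            np.testing.assert_allclose(rec.density, naive.density(), atol=1e-10)
            np.testing.assert_allclose(rec.clustering_coef, naive.clustering(), atol=1e-10)
            np.testing.assert_allclose(rec.avg_path_length, naive.avg_path_length(),
                                       atol=1e-10)
            np.testing.assert_allclose(rec.mean_betweenness, naive.mean_betweenness(),
                                       atol=1e-10)


class TestSampleSubnetwork:
    def _setup(self):
        rng = np.random.default_rng(4)
        table = random_asv_table(rng, n_asvs=12, n_samples=10, depth=60)
        g = rf.build_network(table, NetworkParams(min_mean_rel_abund=0.0,
                                                  r_threshold=0.2, p_threshold=0.5))
        return table, g

    def test_sample_with_every_node_returns_whole_graph(self):
        table, g = self._setup()
        full = AsvTable(counts=table.counts.clip(lower=1), kingdom="bacteria")
        sub = rf.sample_subnetwork(g, full, "s0")
        assert set(sub.nodes) == set(g.nodes)
        assert set(map(frozenset, sub.edges)) == set(map(frozenset, g.edges))

    def test_sample_with_no_nodes_is_empty(self):
        table, g = self._setup()
        zero = AsvTable(counts=table.counts * 0, kingdom="bacteria")
        sub = rf.sample_subnetwork(g, zero, "s0")
        assert sub.number_of_nodes() == 0

    def test_unknown_sample_rejected(self):
        table, g = self._setup()
        with pytest.raises(KeyError, match="nope"):
            rf.sample_subnetwork(g, table, "nope")

    def test_matches_bruteforce_induced_subgraph(self):
        table, g = self._setup()
        for s in table.sample_ids:
            sub = rf.sample_subnetwork(g, table, s)
            present = {a for a in table.asv_ids if table.counts.at[a, s] > 0}
            exp_nodes = {v for v in g.nodes if v in present}
            exp_edges = {frozenset((u, v)) for u, v in g.edges
                         if u in present and v in present}
            assert set(sub.nodes) == exp_nodes
            assert set(map(frozenset, sub.edges)) == exp_edges

    def test_adding_an_asv_never_shrinks_the_subnetwork(self):
        table, g = self._setup()
        s = "s1"
        sub_before = rf.sample_subnetwork(g, table, s)
        richer = table.counts.copy()
        absent = [a for a in table.asv_ids if richer.at[a, s] == 0]
        if absent:
            richer.at[absent[0], s] = 1
        sub_after = rf.sample_subnetwork(
            g, AsvTable(counts=richer, kingdom="bacteria"), s)
        assert sub_after.number_of_nodes() >= sub_before.number_of_nodes()
        assert sub_after.number_of_edges() >= sub_before.number_of_edges()


def _record(graph_id, **overrides) -> TopologyRecord:
    base = dict(n_nodes=10, n_edges=12, n_positive_edges=10, avg_degree=2.4,
                clustering_coef=0.3, avg_path_length=2.0, density=0.27,
                mean_betweenness=0.1)
    base.update(overrides)
    return TopologyRecord(graph_id=graph_id, **base)


class TestComplexityIndex:
    def test_identical_records_share_a_score(self):
        records = [
            _record("a"), _record("b"),
            _record("c", avg_degree=4.0, n_edges=20),
            _record("d", avg_degree=1.0, n_edges=5),
        ]
        res = rf.complexity_index(records)
        np.testing.assert_allclose(res.scores["a"], res.scores["b"], atol=1e-10)

    def test_scores_increase_with_avg_degree_alone(self):
        records = [_record(f"g{k}", avg_degree=1.0 + k) for k in range(5)]
        res = rf.complexity_index(records)
        scores = res.scores[[f"g{k}" for k in range(5)]].to_numpy()
        assert np.all(np.diff(scores) > 0)

    def test_scores_centered_and_oriented_by_degree(self):
        rng = np.random.default_rng(1)
        records = [
            _record(f"g{k}", avg_degree=float(rng.uniform(1, 6)),
                    n_edges=int(rng.integers(5, 30)),
                    clustering_coef=float(rng.uniform(0, 1)))
            for k in range(8)
        ]
        res = rf.complexity_index(records)
        np.testing.assert_allclose(res.scores.mean(), 0.0, atol=1e-10)
        degree = [r.avg_degree for r in records]
        assert np.corrcoef(res.scores, degree)[0, 1] > 0

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            rf.complexity_index([_record("a"), _record("b")])
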