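import itertools
import warnings
from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from hgbench.dyngraph import ConceptNode, EdgeObservation, build_dynamic_graph
from hgbench.importance import (
    COMPONENTS,
    citation_score,
    combine_importance,
    component_correlation,
    edge_betweenness_restricted,
    edge_eigenvector_delta,
    eigenvector_node_centrality,
    mention_score,
    percentile_rank,
    second_order_jaccard,
)

from conftest import make_nodes


# -- independent oracles ------------------------------------------------------


def bc_oracle(G, focus):
    """Exhaustive shortest-path enumeration via networkx."""
    scores = {tuple(sorted(e)): Fraction(0) for e in G.edges()}
    for s, t in itertools.combinations(sorted(focus), 2):
        try:
            paths = list(nx.all_shortest_paths(G, s, t))
        except nx.NetworkXNoPath:
            continue
        sigma = len(paths)
        for p in paths:
            for a, b in zip(p, p[1:]):
                scores[tuple(sorted((a, b)))] += Fraction(1, sigma)
    return scores


def ec_oracle(G, weight="weight"):
    """Dense eigendecomposition per connected component."""
    out = {n: 0.0 for n in G}
    for comp in nx.connected_components(G):
        nodes = sorted(comp)
        if len(nodes) == 1:
            continue
        A = nx.to_numpy_array(G.subgraph(nodes), nodelist=nodes, weight=weight)
        w, v = np.linalg.eigh(A)
        x = v[:, np.argmax(w)]
        if x.sum() < 0:
            x = -x
        for n, val in zip(nodes, x):
            out[n] = float(val)
    return out


def j2_oracle(G, pairs):
    nodes = sorted(G)
    idx = {n: i for i, n in enumerate(nodes)}
    A = nx.to_numpy_array(G, nodelist=nodes) > 0
    A2 = (A @ A) > 0  # reachable in exactly two hops through some neighbour
    out = {}
    for u, v in pairs:
        nu = {nodes[i] for i in np.flatnonzero(A2[idx[u]])}
        nv = {nodes[i] for i in np.flatnonzero(A2[idx[v]])}
        union = nu | nv
        out[tuple(sorted((u, v)))] = len(nu & nv) / len(union) if union else 0.0
    return out


# -- betweenness --------------------------------------------------------------


class TestEdgeBetweenness:
    def test_path_focus_all(self):
        G = nx.path_graph(["a", "b", "c"])
        bc = edge_betweenness_restricted(G, {"a", "b", "c"})
        assert bc[("a", "b")] == 2.0
        assert bc[("b", "c")] == 2.0

    def test_triangle_every_edge_one(self):
        G = nx.complete_graph(["a", "b", "c"])
        bc = edge_betweenness_restricted(G, {"a", "b", "c"})
        assert all(v == 1.0 for v in bc.values())

    def test_path_with_endpoint_focus_only(self):
        G = nx.path_graph(["a", "b", "c", "d"])
        bc = edge_betweenness_restricted(G, {"a", "d"})
        assert all(v == 1.0 for v in bc.values())

    def test_disconnected_pairs_contribute_zero(self):
        G = nx.Graph([("a", "b"), ("x", "y")])
        bc = edge_betweenness_restricted(G, {"a", "x"})
        assert bc[("a", "b")] == 0.0
        assert bc[("x", "y")] == 0.0

    def test_empty_focus_warns_and_zeroes(self):
        G = nx.path_graph(["a", "b", "c"])
        with pytest.warns(UserWarning, match="empty focus"):
            bc = edge_betweenness_restricted(G, set())
        assert set(bc.values()) == {0.0}

    def test_unknown_focus_node_rejected(self):
        G = nx.path_graph(["a", "b"])
        with pytest.raises(ValueError, match="not in graph"):
            edge_betweenness_restricted(G, {"zzz"})

    def test_matches_enumeration_oracle_with_restricted_focus(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            G = nx.gnp_random_graph(14, 0.3, seed=int(rng.integers(2**31)))
            G = nx.relabel_nodes(G, {i: f"n{i:02d}" for i in G})
            focus = set(
                rng.choice(sorted(G), size=min(6, len(G)), replace=False)
            )
            ours = edge_betweenness_restricted(G, focus, exact=True)
            assert ours == bc_oracle(G, focus)


# -- eigenvector centrality ---------------------------------------------------


class TestEigenvectorCentrality:
    def test_complete_graph_uniform(self):
        G = nx.complete_graph(["a", "b", "c", "d"])
        c = eigenvector_node_centrality(G)
        assert all(v == pytest.approx(0.5, abs=1e-10) for v in c.values())

    def test_star_values(self):
        G = nx.star_graph(3)
        c = eigenvector_node_centrality(G)
        assert c[0] == pytest.approx(1 / np.sqrt(2), abs=1e-9)
        for leaf in (1, 2, 3):
            assert c[leaf] == pytest.approx(1 / np.sqrt(6), abs=1e-9)

    def test_two_k2_components_symmetric(self):
        G = nx.Graph([("a", "b"), ("x", "y")])
        c = eigenvector_node_centrality(G)
        assert c["a"] == pytest.approx(c["b"], abs=1e-12)
        assert c["x"] == pytest.approx(c["y"], abs=1e-12)
        assert c["a"] == pytest.approx(1 / np.sqrt(2), abs=1e-9)

    def test_isolated_node_zero(self):
        G = nx.Graph([("a", "b")])
        G.add_node("z")
        assert eigenvector_node_centrality(G)["z"] == 0.0

    def test_weights_matter(self):
        G = nx.Graph()
        G.add_edge("a", "b", weight=10.0)
        G.add_edge("b", "c", weight=1.0)
        c = eigenvector_node_centrality(G)
        assert c["a"] > c["c"]

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            eigenvector_node_centrality(nx.Graph())

    def test_matches_dense_oracle_on_weighted_random_graphs(self):
        rng = np.random.default_rng(9)
        for trial in range(20):
            G = nx.gnp_random_graph(20, 0.2, seed=int(rng.integers(2**31)))
            for u, v in G.edges():
                G[u][v]["weight"] = float(rng.integers(1, 5))
            ours = eigenvector_node_centrality(G)
            ref = ec_oracle(G)
            for n in G:
                assert ours[n] == pytest.approx(ref[n], abs=1e-8)


class TestEigenvectorDelta:
    def test_static_graph_all_zero(self):
        nodes = make_nodes("a", "b", "c")
        obs = [
            EdgeObservation("a", "b", 2000, "d1"),
            EdgeObservation("b", "c", 2000, "d2"),
        ]
        g = build_dynamic_graph(obs, nodes, years=[2000, 2001])
        delta = edge_eigenvector_delta(g, 2000)
        assert all(v == 0.0 for v in delta.values())

    def test_k2_gap_zero_both_years(self):
        nodes = make_nodes("a", "b")
        g = build_dynamic_graph(
            [EdgeObservation("a", "b", 2000, "d1")], nodes, years=[2000, 2001]
        )
        assert edge_eigenvector_delta(g, 2000)[("a", "b")] == 0.0

    def test_pendant_growth_matches_dense_oracle(self):
        nodes = make_nodes("a", "b", "c", "d")
        obs = [
            EdgeObservation("a", "b", 2000, "d1"),
            EdgeObservation("b", "c", 2000, "d2"),
            EdgeObservation("c", "d", 2001, "d3"),
        ]
        g = build_dynamic_graph(obs, nodes)
        delta = edge_eigenvector_delta(g, 2000)
        c0, c1 = ec_oracle(g.snapshot(2000)), ec_oracle(g.snapshot(2001))
        expected = abs(c1["a"] - c1["b"]) - abs(c0["a"] - c0["b"])
        assert delta[("a", "b")] == pytest.approx(expected, abs=1e-9)

    def test_future_year_unavailable_rejected(self, toy_graph):
        with pytest.raises(ValueError):
            edge_eigenvector_delta(toy_graph, 2012)


# -- second-order Jaccard -----------------------------------------------------


class TestSecondOrderJaccard:
    def test_triangle_pair_is_one(self):
        G = nx.complete_graph(["a", "b", "c"])
        assert second_order_jaccard(G, [("a", "b")])[("a", "b")] == 1.0

    def test_path_ends_share_middle_neighbourhood(self):
        G = nx.path_graph(["a", "b", "c"])
        assert second_order_jaccard(G, [("a", "c")])[("a", "c")] == 1.0

    def test_isolated_pair_zero_by_convention(self):
        G = nx.Graph()
        G.add_nodes_from(["u", "v"])
        assert second_order_jaccard(G, [("u", "v")])[("u", "v")] == 0.0

    def test_missing_endpoint_skipped_with_warning(self):
        G = nx.path_graph(["a", "b"])
        with pytest.warns(UserWarning, match="outside the graph"):
            out = second_order_jaccard(G, [("a", "zzz")])
        assert out == {}

    def test_n2_retains_self_when_two_hop_reachable(self):
        # a-b: N2(a) = N(b) = {a}; N2(b) = {b}; J2 = 0 despite adjacency
        G = nx.Graph([("a", "b")])
        assert second_order_jaccard(G, [("a", "b")])[("a", "b")] == 0.0

    def test_matches_matrix_oracle_on_random_graphs(self):
        rng = np.random.default_rng(13)
        for trial in range(20):
            G = nx.gnp_random_graph(15, 0.25, seed=int(rng.integers(2**31)))
            G = nx.relabel_nodes(G, {i: f"n{i:02d}" for i in G})
            pairs = list(itertools.combinations(sorted(G), 2))[:40]
            assert second_order_jaccard(G, pairs) == j2_oracle(G, pairs)

    def test_locality_two_hop_ball(self):
        """Adding an edge at u only changes J2 of pairs within two hops of
        the new edge's endpoints."""
        rng = np.random.default_rng(21)
        G = nx.gnp_random_graph(30, 0.08, seed=3)
        non_edges = [e for e in itertools.combinations(G, 2) if not G.has_edge(*e)]
        u, v = non_edges[int(rng.integers(len(non_edges)))]
        pairs = list(itertools.combinations(G, 2))
        before = second_order_jaccard(G, pairs)
        G2 = G.copy()
        G2.add_edge(u, v)
        after = second_order_jaccard(G2, pairs)
        ball = set(nx.ego_graph(G2, u, radius=2)) | set(nx.ego_graph(G2, v, radius=2))
        for p in pairs:
            if p[0] not in ball and p[1] not in ball:
                assert before[p] == after[p]


# -- literature measures ------------------------------------------------------


class TestLiteratureMeasures:
    def _graph(self):
        nodes = make_nodes("a", "b")
        obs = [
            EdgeObservation("a", "b", 2016, "d1"),
            EdgeObservation("a", "b", 2018, "d2"),
            EdgeObservation("a", "b", 2023, "d3"),
        ]
        return build_dynamic_graph(obs, nodes)

    def test_mentions_counted_up_to_importance_year(self):
        g = self._graph()
        assert mention_score(g, ("a", "b"), 2022) == 2
        assert mention_score(g, ("a", "b"), 2016) == 1

    def test_unknown_edge_warns_and_zero(self):
        g = self._graph()
        with pytest.warns(UserWarning, match="never observed"):
            assert mention_score(g, ("a", "zzz"), 2022) == 0

    def test_citation_sum_with_missing_documents(self):
        from hgbench.dyngraph import CitationGraph

        g = self._graph()
        cit = CitationGraph(
            [("p1", "d1", 2017)] * 1 + [(f"q{i}", "d1", 2018) for i in range(4)]
        )
        # d1 has 5 citations, d2 absent from the citation graph -> 0
        assert citation_score(g, cit, ("a", "b"), 2022) == 5

    def test_citation_score_matches_bruteforce_on_synthetic(self, small_synth):
        _, graph, _, citations = small_synth
        t_imp = graph.years[-1]
        doc_year = graph.documents
        for edge in graph.edges[:25]:
            brute = 0
            for d in graph.edge_documents(edge, t_imp):
                brute += sum(
                    1
                    for citing, cited, year in citations.edges
                    if cited == d and year <= t_imp
                )
            assert citation_score(graph, citations, edge, t_imp) == brute


# -- ranking and combination --------------------------------------------------


class TestPercentileRank:
    def test_three_distinct_values(self):
        assert percentile_rank([1, 2, 3]) == pytest.approx([1 / 6, 1 / 2, 5 / 6])

    def test_all_ties_give_half(self):
        assert percentile_rank([7.0] * 5) == pytest.approx([0.5] * 5)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        perm = rng.permutation(40)
        assert percentile_rank(x)[perm] == pytest.approx(percentile_rank(x[perm]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            percentile_rank([])


def random_raw(n, seed=0, rng=None):
    rng = rng or np.random.default_rng(seed)
    edges = [(f"a{i:03d}", f"b{i:03d}") for i in range(n)]
    return {
        e: {c: float(rng.normal()) for c in COMPONENTS} for e in edges
    }


class TestCombineImportance:
    def test_maximal_edge_gets_maximal_combined(self):
        raw = random_raw(10, seed=4)
        top = ("zz0", "zz1")
        raw[top] = {
            c: (-100.0 if c == "jc2" else 100.0) for c in COMPONENTS
        }
        df = combine_importance(raw)
        n = len(df)
        assert df.loc[[top], "combined"].iloc[0] == pytest.approx((n - 0.5) / n)

    def test_identical_raw_vectors_identical_combined(self):
        raw = random_raw(6, seed=5)
        raw[("x", "y")] = dict(raw[("a000", "b000")])
        df = combine_importance(raw)
        assert df.loc[[("x", "y")], "combined"].iloc[0] == pytest.approx(
            df.loc[[("a000", "b000")], "combined"].iloc[0]
        )

    def test_combined_is_mean_of_six_ranks_and_in_unit_interval(self):
        df = combine_importance(random_raw(25, seed=6))
        pct = df[[f"pct_{c}" for c in COMPONENTS]]
        assert np.allclose(df["combined"], pct.mean(axis=1))
        assert ((df["combined"] > 0) & (df["combined"] < 1)).all()

    def test_invariance_to_monotone_transform_of_any_component(self):
        raw = random_raw(30, seed=7)
        base = combine_importance(raw)
        for comp in COMPONENTS:
            transformed = {
                e: {
                    c: (np.exp(v) if c == comp else v)
                    for c, v in comps.items()
                }
                for e, comps in raw.items()
            }
            df = combine_importance(transformed)
            assert np.allclose(df["combined"], base["combined"])

    def test_lower_jc2_gives_non_decreasing_combined(self):
        raw = random_raw(15, seed=8)
        probe = ("a007", "b007")
        before = combine_importance(raw)
        raw[probe]["jc2"] -= 5.0  # less similar neighbourhoods
        after = combine_importance(raw)
        assert (
            after.loc[[probe], "combined"].iloc[0]
            >= before.loc[[probe], "combined"].iloc[0]
        )

    def test_missing_ig_defaults_to_zero_with_warning(self):
        raw = random_raw(5, seed=9)
        del raw[("a002", "b002")]["ig"]
        with pytest.warns(UserWarning, match="attribution scope"):
            df = combine_importance(raw)
        assert df.loc[[("a002", "b002")], "ig"].iloc[0] == 0.0

    def test_nan_component_rejected_by_name(self):
        raw = random_raw(5, seed=10)
        raw[("a001", "b001")]["ment"] = float("nan")
        with pytest.raises(ValueError, match="ment"):
            combine_importance(raw)


class TestComponentCorrelation:
    def _frame(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({c: rng.normal(size=n) for c in COMPONENTS})

    def test_diagonal_is_one(self):
        mat = component_correlation(self._frame())
        assert np.allclose(np.diag(mat), 1.0)

    def test_monotone_transforms_correlate_perfectly(self):
        df = self._frame()
        df["ec"] = np.exp(df["ig"])  # strictly monotone in ig
        mat = component_correlation(df)
        assert mat.loc["ig", "ec"] == pytest.approx(1.0)

    def test_independent_components_near_zero(self):
        mat = component_correlation(self._frame(n=10000, seed=3))
        assert abs(mat.loc["ig", "cit"]) < 0.05

    def test_constant_component_reported_missing(self):
        df = self._frame()
        df["bc"] = 1.0
        mat = component_correlation(df)
        assert np.isnan(mat.loc["bc", "ig"])
        assert np.isnan(mat.loc["ment", "bc"])

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            component_correlation(self._frame(n=2))
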