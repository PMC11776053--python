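"""Cycle-constrained map construction against a worst-first-removal oracle."""

import networkx as nx
import pytest

from alchemap.fixtures import make_scored_graph
from alchemap.generation import exhaustive_generate
from alchemap.mapbuild import (
    PerturbationMap,
    build_map_from_scored_graph,
    build_pair_map,
    check_constraints,
    extract_ab_subgraph,
    find_bridges,
    map_statistics,
)
from alchemap.pathopt import candidate_graph, find_optimal_path
from alchemap.scoring import score_matrix

from _oracles import pair_map_oracle


def build_abstract(g, a="A", b="B", min_score=0.5, max_dist=3, **kwargs):
    path = find_optimal_path(g, a, b, min_score=min_score, max_dist=max_dist)
    return path, build_map_from_scored_graph(g, a, b, path, **kwargs)


class TestBuildPairMap:
    def test_triangle_closes_the_optimal_link(self):
        g = make_scored_graph(
            edge_score_table={("A", "B"): 0.9, ("A", "X"): 0.7, ("X", "B"): 0.7}
        )
        path, pmap = build_abstract(g)
        assert path.node_ids == ("A", "B")
        assert set(map(tuple, map(sorted, pmap.graph.edges))) == {
            ("A", "B"),
            ("A", "X"),
            ("B", "X"),
        }
        report = check_constraints(pmap, pmap.optimal_links, 4)
        assert all(r["pass"] for r in report.values())

    def test_bare_path_flags_infeasible_links(self):
        g = make_scored_graph(
            edge_score_table={("A", "X"): 0.8, ("X", "B"): 0.8}
        )
        path, pmap = build_abstract(g)
        assert set(pmap.feasibility.values()) == {False}
        assert pmap.warnings  # never a silent pass
        report = check_constraints(pmap, pmap.optimal_links, 4)
        assert not any(r["on_cycle"] for r in report.values())

    def test_optimal_links_always_retained(self):
        g = make_scored_graph(n_nodes=8, seed=3)
        path, pmap = build_abstract(g, "n0", "n1", min_score=0.2, max_dist=3)
        for e in pmap.optimal_links:
            assert pmap.graph.has_edge(*e)
            assert pmap.graph[e[0]][e[1]]["optimal"]

    def test_output_edges_subset_of_pruned_input(self):
        g = make_scored_graph(n_nodes=8, seed=5)
        path, pmap = build_abstract(g, "n0", "n1", min_score=0.2, max_dist=3)
        for u, v in pmap.graph.edges:
            assert g.has_edge(u, v)
            assert g[u][v]["score"] == pmap.graph[u][v]["score"]

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_bruteforce_oracle(self, seed):
        g = make_scored_graph(n_nodes=7, seed=200 + seed)
        try:
            path = find_optimal_path(g, "n0", "n1", min_score=0.3, max_dist=3)
        except Exception:
            pytest.skip("no optimal path in this random instance")
        pmap = build_map_from_scored_graph(
            g, "n0", "n1", path, prune_threshold=0.2, max_cycle=4, max_subgraph_dist=4
        )
        oracle = pair_map_oracle(
            g, "n0", "n1", set(path.edges()), 0.2, 4, 4
        )
        assert set(pmap.graph.nodes) == set(oracle.nodes)
        assert {tuple(sorted(e)) for e in pmap.graph.edges} == {
            tuple(sorted(e)) for e in oracle.edges
        }

    @pytest.mark.parametrize("seed", range(5))
    def test_local_minimality(self, seed):
        """Removing any further non-optimal edge breaks a constraint or
        disconnects the endpoints (it was already attempted)."""
        g = make_scored_graph(n_nodes=7, seed=300 + seed)
        try:
            path = find_optimal_path(g, "n0", "n1", min_score=0.3, max_dist=3)
        except Exception:
            pytest.skip("no optimal path in this random instance")
        pmap = build_map_from_scored_graph(g, "n0", "n1", path)
        from alchemap.mapbuild import _constraints_ok

        for u, v in list(pmap.graph.edges):
            if tuple(sorted((u, v))) in pmap.optimal_links:
                continue
            trial = pmap.graph.copy()
            trial.remove_edge(u, v)
            assert not _constraints_ok(
                trial, pmap.endpoints, pmap.optimal_links, 4, pmap.feasibility
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_each_removal_mode_also_satisfies_constraints(self, seed):
        """The alternative corridor-extraction timing yields a map that
        still retains the optimal links with their cycle cover."""
        from alchemap.mapbuild import _constraints_ok

        g = make_scored_graph(n_nodes=7, seed=400 + seed)
        try:
            path = find_optimal_path(g, "n0", "n1", min_score=0.3, max_dist=3)
        except Exception:
            pytest.skip("no optimal path in this random instance")
        pmap = build_map_from_scored_graph(
            g, "n0", "n1", path, subgraph_mode="each_removal"
        )
        assert _constraints_ok(
            pmap.graph, pmap.endpoints, pmap.optimal_links, 4, pmap.feasibility
        )
        for u, v in pmap.graph.edges:
            assert g.has_edge(u, v)

    def test_unknown_subgraph_mode_rejected(self):
        g = make_scored_graph(edge_score_table={("A", "B"): 0.9})
        path = find_optimal_path(g, "A", "B", min_score=0.0, max_dist=1)
        with pytest.raises(ValueError):
            build_map_from_scored_graph(g, "A", "B", path, subgraph_mode="sometimes")

    def test_chemistry_route_matches_abstract_route(self, mols):
        gen = exhaustive_generate(mols["biphenyl"], mols["phenol"])
        mat = score_matrix(gen.records())
        graph = candidate_graph(gen, 0.0, matrix=mat)
        path = find_optimal_path(graph, "A", "B", min_score=0.5, max_dist=3)
        via_gen = build_pair_map(gen, path, matrix=mat)
        via_graph = build_map_from_scored_graph(graph, "A", "B", path)
        assert set(via_gen.graph.edges) == set(via_graph.graph.edges)


class TestExtractSubgraph:
    def _pmap(self, table, a="A", b="B"):
        g = make_scored_graph(edge_score_table=table)
        return PerturbationMap(
            graph=g, endpoints=(a, b), optimal_links=frozenset(), params={}
        )

    def test_star_collapses_to_hub(self):
        pmap = self._pmap(
            {("A", "H"): 0.9, ("H", "B"): 0.9, ("H", "P"): 0.9, ("P", "Q"): 0.8}
        )
        out = extract_ab_subgraph(pmap, 2)
        assert set(out.graph.nodes) == {"A", "H", "B"}

    def test_idempotent(self):
        pmap = self._pmap({("A", "X"): 0.9, ("X", "B"): 0.9, ("A", "B"): 0.5})
        once = extract_ab_subgraph(pmap, 3)
        twice = extract_ab_subgraph(once, 3)
        assert set(once.graph.nodes) == set(twice.graph.nodes)
        assert set(once.graph.edges) == set(twice.graph.edges)

    def test_pendant_node_removed(self):
        pmap = self._pmap({("A", "B"): 0.9, ("B", "P"): 0.9})
        out = extract_ab_subgraph(pmap, 3)
        assert "P" not in out.graph

    def test_disconnected_endpoints_error(self):
        pmap = self._pmap({("A", "X"): 0.9, ("B", "Y"): 0.9})
        with pytest.raises(nx.NetworkXNoPath):
            extract_ab_subgraph(pmap, 3)


class TestConstraintReport:
    def test_triangle_passes(self):
        g = make_scored_graph(
            edge_score_table={("A", "B"): 0.9, ("A", "X"): 0.7, ("X", "B"): 0.7}
        )
        report = check_constraints(g, {("A", "B")}, 3)
        assert report[("A", "B")]["pass"]

    def test_five_cycle_needs_max_cycle_five(self):
        table = {(f"n{i}", f"n{(i + 1) % 5}"): 0.8 for i in range(5)}
        g = make_scored_graph(edge_score_table=table)
        edge = ("n0", "n1")
        assert not check_constraints(g, {edge}, 4)[edge]["pass"]
        assert check_constraints(g, {edge}, 5)[edge]["pass"]

    def test_missing_link_reported_absent(self):
        g = make_scored_graph(edge_score_table={("A", "X"): 0.9})
        report = check_constraints(g, {("A", "B")}, 4)
        assert not report[("A", "B")]["present"]


class TestBridgesAndStatistics:
    def test_tree_all_bridges_cycle_none(self):
        tree = make_scored_graph(
            edge_score_table={("a", "b"): 0.9, ("b", "c"): 0.9, ("b", "d"): 0.9}
        )
        assert find_bridges(tree) == {("a", "b"), ("b", "c"), ("b", "d")}
        cycle = make_scored_graph(
            edge_score_table={("a", "b"): 0.9, ("b", "c"): 0.9, ("c", "a"): 0.9}
        )
        assert find_bridges(cycle) == set()

    def test_barbell_has_single_bridge(self):
        table = {
            ("a", "b"): 0.9, ("b", "c"): 0.9, ("c", "a"): 0.9,
            ("x", "y"): 0.9, ("y", "z"): 0.9, ("z", "x"): 0.9,
            ("c", "x"): 0.5,
        }
        assert find_bridges(make_scored_graph(edge_score_table=table)) == {("c", "x")}

    def test_triangle_statistics(self):
        g = make_scored_graph(
            edge_score_table={("A", "X"): 0.8, ("X", "B"): 0.7, ("A", "B"): 0.6}
        )
        pmap = PerturbationMap(
            graph=g,
            endpoints=("A", "B"),
            optimal_links=frozenset({("A", "B")}),
            params={},
        )
        stats = map_statistics(pmap)
        assert stats.worst_link_score == pytest.approx(0.6)
        assert stats.ab_distance == 1
        assert stats.n_intermediates == 1
        assert stats.n_links == 3
        assert stats.optimal_path_has_bridge is False

    def test_bare_path_statistics(self):
        g = make_scored_graph(edge_score_table={("A", "X"): 0.8, ("X", "B"): 0.7})
        pmap = PerturbationMap(
            graph=g,
            endpoints=("A", "B"),
            optimal_links=frozenset({("A", "X"), ("B", "X")}),
            params={},
        )
        stats = map_statistics(pmap)
        assert stats.ab_distance == 2
        assert stats.optimal_path_has_bridge is True
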