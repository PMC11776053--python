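"""Series-mode map construction: base build, injection, pruning, fixpoint."""

import itertools

import networkx as nx
import pytest

from alchemap.generation import CompoundRecord
from alchemap.mapbuild import PerturbationMap, _norm, _on_cycle
from alchemap.seriesmap import (
    SeriesBuildState,
    build_base_map,
    build_series_map,
    inject_intermediates,
    prune_intermediates,
    series_summary,
)


class TestBaseMap:
    def test_two_members_single_edge(self, mols):
        recs = [
            CompoundRecord(id="M1", mol=mols["benzene"], role="series_member"),
            CompoundRecord(id="M2", mol=mols["toluene"], role="series_member"),
        ]
        pmap = build_base_map(recs)
        assert list(pmap.graph.edges) == [("M1", "M2")]

    def test_single_member_rejected(self, mols):
        with pytest.raises(ValueError):
            build_base_map(
                [CompoundRecord(id="M1", mol=mols["benzene"], role="series_member")]
            )

    def test_mixed_charges_rejected(self, mols):
        recs = [
            CompoundRecord(id="M1", mol=mols["benzene"], role="series_member"),
            CompoundRecord(id="M2", mol=mols["acetate"], role="series_member"),
        ]
        with pytest.raises(ValueError):
            build_base_map(recs)

    def test_three_similar_members_keep_triangle(self, mols):
        recs = [
            CompoundRecord(id=f"M{i}", mol=mols[n], role="series_member")
            for i, n in enumerate(("toluene", "phenol", "aniline"), start=1)
        ]
        pmap = build_base_map(recs, max_cycle=4)
        # every edge feasible on a triangle, so the cycle constraint keeps all 3
        assert pmap.graph.number_of_edges() == 3

    def test_base_constraints_hold(self, toy_series):
        pmap = build_base_map(toy_series)
        g = pmap.graph
        assert nx.is_connected(g)
        for u, v in itertools.combinations(g.nodes, 2):
            assert nx.shortest_path_length(g, u, v) <= 6
        for u, v in g.edges:
            assert _on_cycle(g, _norm(u, v), 4)


class TestInjection:
    def test_no_bad_edges_is_a_fixpoint(self, close_series):
        pmap = build_base_map(close_series)
        state = SeriesBuildState(pmap=pmap, threshold=0.6)
        assert state.bad_edges() == []
        out = inject_intermediates(state)
        assert set(out.pmap.graph.edges) == set(pmap.graph.edges)
        assert out.pmap.n_intermediates() == 0

    def test_shared_intermediate_added_once(self, toy_series):
        """The distant member has several bad links; a single injected
        compound may repair all of them (dedup by canonical key)."""
        pmap = build_base_map(toy_series)
        state = SeriesBuildState(pmap=pmap, threshold=0.6)
        assert len(state.bad_edges()) >= 2
        out = inject_intermediates(state)
        keys = [
            out.pmap.graph.nodes[n]["record"].mol.canonical_key
            for n, r in out.pmap.graph.nodes(data="role")
            if r == "intermediate"
        ]
        assert len(keys) == len(set(keys))

    def test_intermediates_exempt_from_cycle_constraint(self, toy_series):
        pmap = build_base_map(toy_series)
        state = inject_intermediates(SeriesBuildState(pmap=pmap, threshold=0.6))
        g = state.pmap.graph
        members = {n for n, r in g.nodes(data="role") if r == "series_member"}
        # members all connected and within distance bound
        for u, v in itertools.combinations(members, 2):
            assert nx.shortest_path_length(g, u, v) <= 6


class TestPruning:
    def _abstract_state(self, edges, roles):
        g = nx.Graph()
        for (u, v), s in edges.items():
            g.add_edge(u, v, score=s)
        for n, role in roles.items():
            g.nodes[n]["role"] = role
            g.nodes[n]["record"] = None
        pmap = PerturbationMap(
            graph=g, endpoints=(None, None), optimal_links=frozenset(), params={}
        )
        return SeriesBuildState(pmap=pmap, threshold=0.6)

    def test_pendant_leaf_removed_cycle_kept(self):
        state = self._abstract_state(
            edges={
                ("M1", "M2"): 0.9, ("M2", "M3"): 0.9, ("M3", "M1"): 0.9,
                ("M1", "X1"): 0.8,  # pendant intermediate
                ("M2", "X2"): 0.8, ("M3", "X2"): 0.8,  # intermediate on a cycle
            },
            roles={"M1": "series_member", "M2": "series_member",
                   "M3": "series_member", "X1": "intermediate",
                   "X2": "intermediate"},
        )
        out = prune_intermediates(state)
        assert "X1" not in out.pmap.graph
        assert "X2" in out.pmap.graph

    def test_chain_of_pendants_removed_by_fixpoint(self):
        state = self._abstract_state(
            edges={("M1", "M2"): 0.9, ("M2", "X1"): 0.8, ("X1", "X2"): 0.8},
            roles={"M1": "series_member", "M2": "series_member",
                   "X1": "intermediate", "X2": "intermediate"},
        )
        out = prune_intermediates(state)
        assert set(out.pmap.graph.nodes) == {"M1", "M2"}

    def test_disconnected_intermediate_removed(self):
        state = self._abstract_state(
            edges={("M1", "M2"): 0.9, ("X1", "X2"): 0.8, ("X2", "X3"): 0.8,
                   ("X3", "X1"): 0.8},
            roles={"M1": "series_member", "M2": "series_member",
                   "X1": "intermediate", "X2": "intermediate",
                   "X3": "intermediate"},
        )
        out = prune_intermediates(state)
        assert set(out.pmap.graph.nodes) == {"M1", "M2"}


class TestBuildSeriesMap:
    def test_clean_series_identical_to_base(self, close_series):
        base = build_base_map(close_series)
        pmap, state = build_series_map(close_series, 0.6)
        assert set(pmap.graph.edges) == set(base.graph.edges)
        assert state.iteration == 0

    def test_distant_member_repaired(self, toy_series):
        pmap, state = build_series_map(toy_series, 0.6)
        g = pmap.graph
        members = {n for n, r in g.nodes(data="role") if r == "series_member"}
        assert members == {rec.id for rec in toy_series}
        # all members in one component
        assert all(
            nx.has_path(g, u, v) for u, v in itertools.combinations(members, 2)
        )
        # no member-member edge below threshold (unless flagged failed)
        for u, v, s in g.edges(data="score"):
            if u in members and v in members and _norm(u, v) not in state.failed_edges:
                assert s >= 0.6
        # intermediates are neither leaves nor disconnected
        for n, r in g.nodes(data="role"):
            if r == "intermediate":
                assert g.degree(n) >= 2
        assert pmap.n_intermediates() >= 1

    def test_summary_counts(self, toy_series):
        pmap, _ = build_series_map(toy_series, 0.6)
        summary = series_summary(pmap)
        assert summary["n_members"] == len(toy_series)
        assert summary["n_links_le_0.4"] == 0
        assert summary["n_links"] == pmap.graph.number_of_edges()

    def test_deterministic_edge_for_edge(self, toy_series):
        p1, s1 = build_series_map(toy_series, 0.6)
        p2, s2 = build_series_map(toy_series, 0.6)
        assert sorted(p1.graph.edges) == sorted(p2.graph.edges)
        assert s1.log == s2.log

    def test_bad_edge_multiset_never_grows(self, toy_series):
        """Monotone progress: injection never adds new sub-threshold
        member-member edges."""
        base = build_base_map(toy_series)
        state = SeriesBuildState(pmap=base, threshold=0.6)
        n_bad = len(state.bad_edges())
        for _ in range(3):
            new_state = prune_intermediates(inject_intermediates(state))
            n_new = len(new_state.bad_edges())
            assert n_new <= n_bad
            n_bad, state = n_new, new_state
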