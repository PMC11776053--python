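"""Perturbation maps for congeneric series with injected intermediates.

A base map over the series members is built Lomap-style: all pairs are
scored, then edges are removed worst-first as long as the graph stays
connected, every member stays within a distance bound of every other, and
each retained member-member edge lies on a small cycle where one exists.

Edges between members whose link score falls below the series threshold are
then repaired by pair-mode intermediate injection: for each such edge,
intermediates are generated exhaustively between its endpoints, the optimal
intermediate path is computed, and its nodes are added to the compound set
(deduplicated by canonical key).  The map is rebuilt incrementally — only
edges between the new intermediates and existing nodes are added — under
modified constraints that do not check connectivity, distance, or cyclicity
for intermediates.  Intermediates that end up disconnected from the main
graph or as acyclic leaves are pruned.  The loop repeats until no
member-member edge scores below the threshold (or an iteration cap is hit,
in which case the remaining bad edges are flagged).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import networkx as nx

from .generation import CompoundRecord, GenerationOverflowError, exhaustive_generate
from .mapbuild import Edge, PerturbationMap, _norm, _on_cycle
from .pathopt import PathNotFoundError, candidate_graph, find_optimal_path
from .scoring import link_score

logger = logging.getLogger(__name__)


@dataclass
class SeriesBuildState:
    pmap: PerturbationMap
    threshold: float
    iteration: int = 0
    attempted_edges: set[Edge] = field(default_factory=set)
    failed_edges: set[Edge] = field(default_factory=set)
    log: list[dict] = field(default_factory=list)

    def member_ids(self) -> list[str]:
        return [
            n
            for n, role in self.pmap.graph.nodes(data="role")
            if role == "series_member"
        ]

    def bad_edges(self) -> list[Edge]:
        """Member-member edges scoring below the threshold, worst first."""
        members = set(self.member_ids())
        bad = [
            (_norm(u, v), s)
            for u, v, s in self.pmap.graph.edges(data="score")
            if u in members and v in members and s < self.threshold
        ]
        bad.sort(key=lambda t: (t[1], t[0]))
        return [e for e, _ in bad]


# ---------------------------------------------------------------------------
# Lomap-style constrained removal
# ---------------------------------------------------------------------------


def _series_constraints_ok(
    graph: nx.Graph,
    members: list[str],
    max_cycle: int,
    d_max: int,
    feasibility: dict[Edge, bool],
) -> bool:
    """Constraints checked for members only; intermediates are exempt."""
    if not members:
        return True
    comp = None
    for m in members:
        if m not in graph:
            return False
        if comp is None:
            comp = nx.node_connected_component(graph, m)
        elif m not in comp:
            return False
    for u, v in itertools.combinations(members, 2):
        try:
            if nx.shortest_path_length(graph, u, v) > d_max:
                return False
        except nx.NetworkXNoPath:
            return False
    member_set = set(members)
    for u, v in graph.edges:
        if u in member_set and v in member_set:
            e = _norm(u, v)
            if feasibility.get(e, False) and not _on_cycle(graph, e, max_cycle):
                return False
    return True


def _worst_first_removal(
    graph: nx.Graph,
    members: list[str],
    max_cycle: int,
    d_max: int,
) -> nx.Graph:
    member_set = set(members)
    feasibility = {
        _norm(u, v): _on_cycle(graph, _norm(u, v), max_cycle)
        for u, v in graph.edges
        if u in member_set and v in member_set
    }
    order = sorted(
        ((graph[u][v]["score"], _norm(u, v)) for u, v in graph.edges),
        key=lambda t: (t[0], t[1]),
    )
    for _, edge in order:
        if not graph.has_edge(*edge):
            continue
        attrs = graph[edge[0]][edge[1]]
        graph.remove_edge(*edge)
        if not _series_constraints_ok(graph, members, max_cycle, d_max, feasibility):
            graph.add_edge(*edge, **attrs)
    return graph


def build_base_map(
    members: list[CompoundRecord],
    *,
    beta: float = 0.1,
    max_cycle: int = 4,
    d_max: int = 6,
    matrix=None,
) -> PerturbationMap:
    """Lomap-style map over the series members (no intermediates yet)."""
    if len(members) < 2:
        raise ValueError("a series needs at least two members")
    charges = {rec.mol.net_charge for rec in members}
    if len(charges) != 1:
        raise ValueError(f"series members must share one net charge, got {charges}")
    members = [replace(rec, role="series_member") for rec in members]
    g = candidate_graph(members, 0.0, matrix=matrix, beta=beta)
    member_ids = [rec.id for rec in members]
    g = _worst_first_removal(g, member_ids, max_cycle, d_max)
    return PerturbationMap(
        graph=g,
        endpoints=(None, None),
        optimal_links=frozenset(),
        params={"beta": beta, "max_cycle": max_cycle, "d_max": d_max},
    )


# ---------------------------------------------------------------------------
# intermediate injection
# ---------------------------------------------------------------------------


def inject_intermediates(
    state: SeriesBuildState,
    threshold: float | None = None,
    *,
    max_dist: int = 3,
    mcs_timeout: int = 60,
) -> SeriesBuildState:
    """Repair all current bad edges by optimal-path intermediate injection.

    For each member-member edge below the threshold, pair-mode generation is
    run on its endpoints and the optimal path's intermediates are appended
    (deduplicated against every compound already in the map).  New link
    scores are computed only between the injected intermediates and existing
    nodes, then a worst-first removal pass with the intermediate-exempt
    constraints rebuilds the map.  An edge whose path search fails is kept,
    flagged, and excluded from further attempts.
    """
    threshold = state.threshold if threshold is None else threshold
    pmap = state.pmap
    g = pmap.graph
    params = pmap.params
    beta = params.get("beta", 0.1)
    max_cycle = params.get("max_cycle", 4)
    d_max = params.get("d_max", 6)

    records = {n: g.nodes[n]["record"] for n in g.nodes}
    existing_keys = {rec.mol.canonical_key: nid for nid, rec in records.items()}
    counter = sum(1 for r in records.values() if r.role == "intermediate")

    bad = [e for e in state.bad_edges() if e not in state.attempted_edges]
    attempted = set(state.attempted_edges)
    failed = set(state.failed_edges)
    new_records: list[CompoundRecord] = []

    for edge in bad:
        attempted.add(edge)
        u, v = edge
        try:
            gen = exhaustive_generate(
                records[u], records[v], mcs_timeout=mcs_timeout
            )
            pair_graph = candidate_graph(gen, min(threshold, 1.0), beta=beta)
            path = find_optimal_path(
                pair_graph, u, v, min_score=threshold, max_dist=max_dist
            )
        except (PathNotFoundError, GenerationOverflowError) as exc:
            logger.warning("no repair path for %s--%s: %s", u, v, exc)
            failed.add(edge)
            continue
        for nid in path.node_ids[1:-1]:
            rec = gen.by_id()[nid]
            key = rec.mol.canonical_key
            if key in existing_keys:
                continue  # already in the map (member or earlier intermediate)
            counter += 1
            new_id = f"X{counter}"
            new_rec = CompoundRecord(
                id=new_id,
                mol=rec.mol,
                role="intermediate",
                provenance=rec.provenance,
                direction=rec.direction,
            )
            existing_keys[key] = new_id
            records[new_id] = new_rec
            new_records.append(new_rec)

    # incremental rebuild: new edges only between intermediates and existing
    new_graph = g.copy()
    existing_ids = list(g.nodes)
    for rec in new_records:
        new_graph.add_node(
            rec.id, record=rec, smiles=rec.mol.canonical_key, role=rec.role
        )
    for i, rec in enumerate(new_records):
        partners = existing_ids + [r.id for r in new_records[:i]]
        for other in partners:
            s = link_score(
                rec.mol, records[other].mol, beta, timeout=mcs_timeout
            ).value
            new_graph.add_edge(rec.id, other, score=s)

    member_ids = [n for n, r in new_graph.nodes(data="role") if r == "series_member"]
    new_graph = _worst_first_removal(new_graph, member_ids, max_cycle, d_max)

    new_pmap = PerturbationMap(
        graph=new_graph,
        endpoints=pmap.endpoints,
        optimal_links=pmap.optimal_links,
        params=dict(params),
        warnings=list(pmap.warnings),
    )
    log = list(state.log)
    log.append(
        {
            "iteration": state.iteration + 1,
            "bad_edges": [f"{u}--{v}" for u, v in bad],
            "injected": [rec.id for rec in new_records],
            "failed": [f"{u}--{v}" for u, v in sorted(failed)],
        }
    )
    return SeriesBuildState(
        pmap=new_pmap,
        threshold=state.threshold,
        iteration=state.iteration + 1,
        attempted_edges=attempted,
        failed_edges=failed,
        log=log,
    )


def prune_intermediates(state: SeriesBuildState) -> SeriesBuildState:
    """Drop intermediates that are disconnected from the members or are
    acyclic leaves; iterates to a fixpoint."""
    g = state.pmap.graph.copy()
    members = [n for n, r in g.nodes(data="role") if r == "series_member"]
    while True:
        main = set()
        for m in members:
            main |= nx.node_connected_component(g, m)
        doomed = [
            n
            for n, r in g.nodes(data="role")
            if r == "intermediate" and (n not in main or g.degree(n) <= 1)
        ]
        if not doomed:
            break
        g.remove_nodes_from(doomed)
    new_pmap = PerturbationMap(
        graph=g,
        endpoints=state.pmap.endpoints,
        optimal_links=state.pmap.optimal_links,
        params=dict(state.pmap.params),
        warnings=list(state.pmap.warnings),
    )
    return replace(state, pmap=new_pmap)


def build_series_map(
    members: list[CompoundRecord],
    threshold: float = 0.6,
    *,
    beta: float = 0.1,
    max_cycle: int = 4,
    d_max: int = 6,
    max_dist: int = 3,
    max_iterations: int = 5,
    mcs_timeout: int = 60,
    matrix=None,
) -> tuple[PerturbationMap, SeriesBuildState]:
    """Iterate inject/rebuild/prune until no member-member edge is bad.

    Returns the final map and the build state (iteration log, flagged
    edges).  Remaining sub-threshold member-member edges, if any, carry a
    ``below_threshold`` edge attribute and a warning.
    """
    base = build_base_map(
        members, beta=beta, max_cycle=max_cycle, d_max=d_max, matrix=matrix
    )
    state = SeriesBuildState(pmap=base, threshold=threshold)
    while state.iteration < max_iterations:
        remaining = [e for e in state.bad_edges() if e not in state.attempted_edges]
        if not remaining:
            break
        state = inject_intermediates(
            state, threshold, max_dist=max_dist, mcs_timeout=mcs_timeout
        )
        state = prune_intermediates(state)

    leftovers = state.bad_edges()
    for u, v in leftovers:
        state.pmap.graph[u][v]["below_threshold"] = True
        state.pmap.warnings.append(
            f"member link {u}--{v} remains below threshold {threshold}"
        )
    return state.pmap, state


def series_summary(pmap: PerturbationMap) -> dict:
    """Node/link counts plus tallies of weak links (score <= 0.6 / <= 0.4)."""
    scores = [s for _, _, s in pmap.graph.edges(data="score")]
    return {
        "n_nodes": pmap.graph.number_of_nodes(),
        "n_members": sum(
            1 for _, r in pmap.graph.nodes(data="role") if r == "series_member"
        ),
        "n_intermediates": pmap.n_intermediates(),
        "n_links": len(scores),
        "n_links_le_0.6": sum(1 for s in scores if s <= 0.6),
        "n_links_le_0.4": sum(1 for s in scores if s <= 0.4),
    }


__all__ = [
    "SeriesBuildState",
    "build_base_map",
    "inject_intermediates",
    "prune_intermediates",
    "build_series_map",
    "series_summary",
]
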