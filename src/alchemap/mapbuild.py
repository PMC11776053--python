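"""Pair perturbation-map construction.

Starting from the scored candidate graph (edges below a prune threshold are
dropped), edges are sorted worst-first and removal of each is attempted.  A
removal is kept only if the map still satisfies two constraints:

1. every optimal link (edge of the optimal intermediate path) is retained;
2. every optimal link lies on a cycle of size <= MAX_CYCLE, so each planned
   transformation can be checked against a closed thermodynamic cycle.

Finally only the nodes lying on simple A->B paths within
MAX_SUBGRAPH_DIST are kept, which discards intermediates the map does not
need.  If for some optimal link no qualifying cycle exists even in the full
pruned graph, the link is flagged infeasible and reported, never silently
passed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import networkx as nx
import pandas as pd

from .generation import GenerationResult
from .pathopt import TransformationPath, candidate_graph

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


def _norm(u: str, v: str) -> Edge:
    return (u, v) if u <= v else (v, u)


@dataclass
class PerturbationMap:
    """A scored compound graph with designated endpoints.

    ``graph`` nodes carry ``smiles`` and ``role`` attributes (and ``record``
    when built in-process); edges carry ``score`` and an ``optimal`` flag.
    ``feasibility`` records, per optimal link, whether a cycle of size
    <= MAX_CYCLE existed in the pruned candidate graph at all.
    """

    graph: nx.Graph
    endpoints: tuple[str | None, str | None]
    optimal_links: frozenset[Edge]
    params: dict
    feasibility: dict[Edge, bool] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def a_id(self) -> str | None:
        return self.endpoints[0]

    @property
    def b_id(self) -> str | None:
        return self.endpoints[1]

    def edge_score(self, u: str, v: str) -> float:
        return self.graph[u][v]["score"]

    def n_intermediates(self) -> int:
        """Nodes labelled as intermediates; on role-less (abstract) graphs,
        every non-endpoint node counts."""
        count = 0
        for node, role in self.graph.nodes(data="role"):
            if role is None:
                count += node not in self.endpoints
            else:
                count += role == "intermediate"
        return count


class MapStatistics(NamedTuple):
    worst_link_score: float
    ab_distance: int
    n_intermediates: int
    n_links: int
    optimal_path_has_bridge: bool


def _on_cycle(graph: nx.Graph, edge: Edge, max_cycle: int) -> bool:
    """True if ``edge`` lies on a cycle of size <= max_cycle.

    Equivalent to an alternative path between its endpoints of length
    <= max_cycle - 1 once the edge itself is set aside.
    """
    u, v = edge
    if not graph.has_edge(u, v):
        return False
    without = nx.restricted_view(graph, [], [(u, v)])
    try:
        return nx.shortest_path_length(without, u, v) <= max_cycle - 1
    except nx.NetworkXNoPath:
        return False


def check_constraints(
    pmap: "PerturbationMap | nx.Graph",
    optimal_links: Iterable[Edge],
    max_cycle: int,
) -> dict:
    """Per-optimal-link constraint report: presence and cycle membership."""
    graph = pmap.graph if isinstance(pmap, PerturbationMap) else pmap
    report: dict[Edge, dict] = {}
    for edge in sorted(_norm(*e) for e in optimal_links):
        present = graph.has_edge(*edge)
        on_cycle = present and _on_cycle(graph, edge, max_cycle)
        report[edge] = {
            "present": present,
            "on_cycle": on_cycle,
            "pass": present and on_cycle,
        }
    return report


def _constraints_ok(
    graph: nx.Graph,
    endpoints: tuple[str, str],
    optimal_links: frozenset[Edge],
    max_cycle: int,
    feasibility: dict[Edge, bool],
) -> bool:
    a, b = endpoints
    if a not in graph or b not in graph:
        return False
    if not nx.has_path(graph, a, b):
        return False
    for edge in optimal_links:
        if not graph.has_edge(*edge):
            return False
        if feasibility.get(edge, True) and not _on_cycle(graph, edge, max_cycle):
            return False
    return True


def _corridor_nodes(graph: nx.Graph, a: str, b: str, max_dist: int) -> set[str]:
    nodes: set[str] = set()
    for path in nx.all_simple_paths(graph, a, b, cutoff=max_dist):
        nodes.update(path)
    return nodes


def extract_ab_subgraph(
    pmap: PerturbationMap, max_subgraph_dist: int
) -> PerturbationMap:
    """Keep only nodes on simple A->B paths of length <= max_subgraph_dist.

    Induced edges are retained; the operation is idempotent.  Raises if the
    endpoints are disconnected.
    """
    a, b = pmap.endpoints
    if a is None or b is None:
        raise ValueError("subgraph extraction requires designated endpoints")
    if not nx.has_path(pmap.graph, a, b):
        raise nx.NetworkXNoPath(f"endpoints {a} and {b} are disconnected")
    nodes = _corridor_nodes(pmap.graph, a, b, max_subgraph_dist)
    sub = pmap.graph.subgraph(nodes).copy()
    return PerturbationMap(
        graph=sub,
        endpoints=pmap.endpoints,
        optimal_links=pmap.optimal_links,
        params=dict(pmap.params),
        feasibility=dict(pmap.feasibility),
        warnings=list(pmap.warnings),
    )


def build_pair_map(
    candidates: GenerationResult,
    optimal: TransformationPath,
    *,
    prune_threshold: float = 0.2,
    max_cycle: int = 4,
    max_subgraph_dist: int = 4,
    subgraph_mode: str = "finalize",
    matrix: pd.DataFrame | None = None,
    beta: float = 0.1,
) -> PerturbationMap:
    """Construct the pair perturbation map around the optimal path.

    ``subgraph_mode`` selects when the A->B corridor subgraph is extracted:
    ``"finalize"`` (default) extracts once after the removal pass;
    ``"each_removal"`` re-extracts after every kept removal before the
    constraint check.
    """
    g = candidate_graph(candidates, prune_threshold, matrix=matrix, beta=beta)
    return build_map_from_scored_graph(
        g,
        candidates.a_id,
        candidates.b_id,
        optimal,
        prune_threshold=prune_threshold,
        max_cycle=max_cycle,
        max_subgraph_dist=max_subgraph_dist,
        subgraph_mode=subgraph_mode,
        beta=beta,
    )


def build_map_from_scored_graph(
    g: nx.Graph,
    a_id: str,
    b_id: str,
    optimal: TransformationPath,
    *,
    prune_threshold: float = 0.2,
    max_cycle: int = 4,
    max_subgraph_dist: int = 4,
    subgraph_mode: str = "finalize",
    beta: float = 0.1,
) -> PerturbationMap:
    """Removal pass and corridor extraction on an already-scored graph.

    ``g`` is consumed (edges are removed in place on a copy).  Edges below
    ``prune_threshold`` are dropped up front; optimal links are exempt.
    """
    if subgraph_mode not in ("finalize", "each_removal"):
        raise ValueError(f"unknown subgraph_mode: {subgraph_mode!r}")
    g = g.copy()
    optimal_links = frozenset(_norm(u, v) for u, v in optimal.edges())
    g.remove_edges_from(
        [
            (u, v)
            for u, v, s in g.edges(data="score")
            if s < prune_threshold and _norm(u, v) not in optimal_links
        ]
    )
    # optimal links are part of the map by definition, even if a fallback
    # path dipped below the prune threshold
    for (u, v), s in zip(optimal.edges(), optimal.edge_scores):
        if not g.has_edge(u, v):
            g.add_edge(u, v, score=s)
    nx.set_edge_attributes(g, False, "optimal")
    for u, v in optimal_links:
        g[u][v]["optimal"] = True

    feasibility = {e: _on_cycle(g, e, max_cycle) for e in optimal_links}
    warnings: list[str] = []
    for e, ok in sorted(feasibility.items()):
        if not ok:
            warnings.append(
                f"optimal link {e[0]}--{e[1]} lies on no cycle of size <= "
                f"{max_cycle} even in the full pruned graph"
            )

    params = {
        "prune_threshold": prune_threshold,
        "max_cycle": max_cycle,
        "max_subgraph_dist": max_subgraph_dist,
        "subgraph_mode": subgraph_mode,
        "beta": beta,
    }

    # worst-first removal pass
    order = sorted(
        ((g[u][v]["score"], _norm(u, v)) for u, v in g.edges), key=lambda t: (t[0], t[1])
    )
    for _, edge in order:
        if edge in optimal_links:
            continue  # constraint 1: optimal links are never removed
        if not g.has_edge(*edge):
            continue  # vanished with an extracted-away node
        attrs = g[edge[0]][edge[1]]
        g.remove_edge(*edge)
        if subgraph_mode == "each_removal":
            try:
                nodes = _corridor_nodes(g, a_id, b_id, max_subgraph_dist)
            except nx.NodeNotFound:
                nodes = set()
            trial = g.subgraph(nodes).copy() if nodes else g
            if nodes and _constraints_ok(
                trial, (a_id, b_id), optimal_links, max_cycle, feasibility
            ):
                g = trial
            else:
                g.add_edge(*edge, **attrs)
        else:
            if not _constraints_ok(
                g, (a_id, b_id), optimal_links, max_cycle, feasibility
            ):
                g.add_edge(*edge, **attrs)

    pmap = PerturbationMap(
        graph=g,
        endpoints=(a_id, b_id),
        optimal_links=optimal_links,
        params=params,
        feasibility=feasibility,
        warnings=warnings,
    )
    # finalization pass: extract the A->B corridor, keep it only if the
    # constraints survive the extraction
    extracted = extract_ab_subgraph(pmap, max_subgraph_dist)
    if _constraints_ok(
        extracted.graph, (a_id, b_id), optimal_links, max_cycle, feasibility
    ):
        pmap = extracted
    elif extracted.graph.number_of_nodes() != g.number_of_nodes():
        pmap.warnings.append(
            "corridor extraction skipped: it would break a cycle constraint"
        )
        # still drop nodes that cannot reach the endpoints at all
        keep = nx.node_connected_component(g, a_id)
        pmap.graph = g.subgraph(keep).copy()
    return pmap


def find_bridges(pmap: "PerturbationMap | nx.Graph") -> set[Edge]:
    """Edges lying on no cycle (cut edges) of the map."""
    graph = pmap.graph if isinstance(pmap, PerturbationMap) else pmap
    return {_norm(u, v) for u, v in nx.bridges(graph)}


def map_statistics(pmap: PerturbationMap) -> MapStatistics:
    """The five summary statistics of a pair map.

    Worst link score, A-B graph distance, number of intermediates, number
    of links, and whether any optimal link is a bridge.
    """
    a, b = pmap.endpoints
    bridges = find_bridges(pmap)
    scores = [s for _, _, s in pmap.graph.edges(data="score")]
    return MapStatistics(
        worst_link_score=min(scores) if scores else float("nan"),
        ab_distance=nx.shortest_path_length(pmap.graph, a, b),
        n_intermediates=pmap.n_intermediates(),
        n_links=pmap.graph.number_of_edges(),
        optimal_path_has_bridge=any(e in bridges for e in pmap.optimal_links),
    )


__all__ = [
    "PerturbationMap",
    "MapStatistics",
    "build_pair_map",
    "build_map_from_scored_graph",
    "extract_ab_subgraph",
    "check_constraints",
    "find_bridges",
    "map_statistics",
]
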