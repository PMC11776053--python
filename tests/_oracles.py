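"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: common-substructure
search is done by explicit subset enumeration + monomorphism, path search by
a hand-rolled DFS with the path score written in its expanded
harmonic-mean-of-squares form, and cycle membership by enumerating simple
cycles.  They are only suitable for small inputs.
"""

from __future__ import annotations

import itertools

import networkx as nx
from networkx.algorithms import isomorphism

from alchemap.chemgraph import Molecule


def mol_to_nx(mol: Molecule) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.rdmol.GetAtoms():
        g.add_node(
            atom.GetIdx(),
            element=atom.GetSymbol(),
            charge=atom.GetFormalCharge(),
            in_ring=atom.IsInRing(),
        )
    for bond in mol.rdmol.GetBonds():
        g.add_edge(
            bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), in_ring=bond.IsInRing()
        )
    return g


def _largest_common_connected(
    ga: nx.Graph, gb: nx.Graph, element_match: bool, ring_constraint: bool
) -> int:
    """Size of the largest connected subset of A monomorphic into B."""

    def node_match(nb, na):
        if element_match and nb["element"] != na["element"]:
            return False
        if ring_constraint and nb["in_ring"] != na["in_ring"]:
            return False
        return True

    def edge_match(eb, ea):
        return not ring_constraint or eb["in_ring"] == ea["in_ring"]

    nodes = list(ga.nodes)
    for size in range(min(len(nodes), len(gb)), 0, -1):
        for subset in itertools.combinations(nodes, size):
            sub = ga.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            gm = isomorphism.GraphMatcher(
                gb, sub, node_match=node_match, edge_match=edge_match
            )
            if gm.subgraph_is_monomorphic():
                return size
    return 0


def mcs_size_oracle(
    a: Molecule, b: Molecule, allow_element_mismatch: bool = True
) -> int:
    """Exhaustive maximum connected common-substructure size (atoms).

    Mirrors the advertised matching flavor: ring atoms/bonds only map to
    ring atoms/bonds, elements are ignored when mismatch is allowed; when
    nothing qualifies, the mapping degenerates to a single-atom anchor.
    """
    ga, gb = mol_to_nx(a), mol_to_nx(b)
    best = _largest_common_connected(ga, gb, not allow_element_mismatch, True)
    if best == 0:
        # bondless single-atom anchor: the ring rule is vacuous on one atom
        best = min(1, _largest_common_connected(ga, gb, not allow_element_mismatch, False))
    return best


# ---------------------------------------------------------------------------
# path search
# ---------------------------------------------------------------------------


def path_score_expanded(scores: list[float]) -> float:
    """Harmonic mean of the squared link scores divided by the path length."""
    n = len(scores)
    harmonic_mean_of_squares = n / sum(1.0 / s**2 for s in scores)
    return harmonic_mean_of_squares / n


def enumerate_simple_paths(graph: nx.Graph, a, b, max_len: int):
    """All simple a->b paths with <= max_len edges (hand-rolled DFS)."""
    out = []

    def dfs(node, path):
        if node == b:
            out.append(list(path))
            return
        if len(path) - 1 >= max_len:
            return
        for nbr in sorted(graph.neighbors(node)):
            if nbr not in path:
                path.append(nbr)
                dfs(nbr, path)
                path.pop()

    dfs(a, [a])
    return out


def optimal_path_oracle(graph: nx.Graph, a, b, min_score: float, max_dist: int):
    """argmax of the path score over all qualifying simple paths.

    Tie rules: higher score, then shorter, then higher worst link, then
    lexicographically smallest node sequence.  Returns (nodes, score) or
    None.
    """
    best = None
    for nodes in enumerate_simple_paths(graph, a, b, max_dist):
        scores = [graph[u][v]["score"] for u, v in zip(nodes, nodes[1:])]
        if any(s < min_score for s in scores):
            continue
        value = path_score_expanded(scores)
        key = (-value, len(scores), -min(scores), tuple(nodes))
        if best is None or key < best[0]:
            best = (key, nodes, value)
    if best is None:
        return None
    return best[1], best[2]


# ---------------------------------------------------------------------------
# map construction
# ---------------------------------------------------------------------------


def edge_on_small_cycle(graph: nx.Graph, edge, max_cycle: int) -> bool:
    """Naive check by enumerating all simple cycles up to max_cycle."""
    u, v = edge
    for cycle in nx.simple_cycles(graph, length_bound=max_cycle):
        ring = set(zip(cycle, cycle[1:] + cycle[:1]))
        if (u, v) in ring or (v, u) in ring:
            return True
    return False


def pair_map_oracle(
    graph: nx.Graph,
    a,
    b,
    optimal_edges: set,
    prune_threshold: float,
    max_cycle: int,
    max_subgraph_dist: int,
) -> nx.Graph:
    """Worst-first removal with the same tie rules, naive primitives."""
    g = graph.copy()
    norm = lambda e: tuple(sorted(e))
    optimal = {norm(e) for e in optimal_edges}
    for u, v, s in list(g.edges(data="score")):
        if s < prune_threshold and norm((u, v)) not in optimal:
            g.remove_edge(u, v)
    feasible = {e: edge_on_small_cycle(g, e, max_cycle) for e in optimal}

    def ok(h):
        if a not in h or b not in h or not nx.has_path(h, a, b):
            return False
        for e in optimal:
            if not h.has_edge(*e):
                return False
            if feasible[e] and not edge_on_small_cycle(h, e, max_cycle):
                return False
        return True

    order = sorted((g[u][v]["score"], norm((u, v))) for u, v in g.edges)
    for _, e in order:
        if e in optimal or not g.has_edge(*e):
            continue
        data = dict(g[e[0]][e[1]])
        g.remove_edge(*e)
        if not ok(g):
            g.add_edge(*e, **data)

    corridor = set()
    for nodes in enumerate_simple_paths(g, a, b, max_subgraph_dist):
        corridor.update(nodes)
    sub = g.subgraph(corridor).copy()
    if ok(sub):
        return sub
    if set(sub.nodes) == set(g.nodes):
        return sub
    return g.subgraph(nx.node_connected_component(g, a)).copy()
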