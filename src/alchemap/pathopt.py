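"""Optimal intermediate-path selection.

Among all simple paths from ligand A to ligand B whose edges all have link
score >= MIN_SCORE and whose length (edge count) is <= MAX_DIST, the optimal
intermediate path is the one with the highest path score.  The two
thresholds keep the path short (error accumulation grows with length) and
free of hard-to-simulate links.  Candidate graphs are small, so the search
is an exhaustive depth-bounded enumeration of simple paths.

Ties are broken by shorter length, then higher worst link, then
lexicographically smallest node-id sequence, so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .generation import GenerationResult
from .scoring import PathScore, path_score, score_matrix


class PathNotFoundError(RuntimeError):
    """No qualifying path exists.

    Carries ``fallback``: the best-effort path that maximizes the worst link
    within MAX_DIST ignoring MIN_SCORE (flagged), or None if the endpoints
    are not connected within MAX_DIST at all.
    """

    def __init__(self, message: str, fallback: "TransformationPath | None" = None):
        super().__init__(message)
        self.fallback = fallback


@dataclass(frozen=True)
class TransformationPath:
    """An ordered A -> B compound sequence with its per-edge link scores."""

    node_ids: tuple[str, ...]
    edge_scores: tuple[float, ...]
    score: PathScore
    fallback: bool = False

    @property
    def worst_link(self) -> float:
        return min(self.edge_scores)

    @property
    def length(self) -> int:
        return len(self.node_ids) - 1

    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.node_ids, self.node_ids[1:]))


def candidate_graph(
    candidates: GenerationResult | list,
    min_score: float,
    *,
    matrix: pd.DataFrame | None = None,
    beta: float = 0.1,
) -> nx.Graph:
    """Scored graph over candidates keeping only edges with S_e >= min_score.

    ``matrix`` may be a precomputed :func:`alchemap.scoring.score_matrix`;
    otherwise it is computed here.  Node ids are compound ids; each node
    carries its record, each edge its ``score``.
    """
    records = (
        candidates.records() if isinstance(candidates, GenerationResult) else list(candidates)
    )
    if matrix is None:
        matrix = score_matrix(records, beta)
    g = nx.Graph()
    for rec in records:
        g.add_node(rec.id, record=rec, smiles=rec.mol.canonical_key, role=rec.role)
    for i, ri in enumerate(records):
        for rj in records[i + 1 :]:
            s = float(matrix.loc[ri.id, rj.id])
            if s >= min_score:
                g.add_edge(ri.id, rj.id, score=s)
    return g


def _evaluate(graph: nx.Graph, nodes: list[str]) -> TransformationPath:
    scores = tuple(graph[u][v]["score"] for u, v in zip(nodes, nodes[1:]))
    return TransformationPath(
        node_ids=tuple(nodes), edge_scores=scores, score=path_score(scores)
    )


def find_optimal_path(
    graph: nx.Graph,
    a_id: str,
    b_id: str,
    min_score: float = 0.0,
    max_dist: int = 3,
) -> TransformationPath:
    """Highest-path-score simple A->B path under MIN_SCORE and MAX_DIST.

    Raises :class:`PathNotFoundError` when no path qualifies; the exception
    carries a flagged best-effort path (maximal worst link within MAX_DIST,
    ignoring MIN_SCORE) when one exists.
    """
    if a_id == b_id:
        raise ValueError("endpoints must be distinct compounds")
    if a_id not in graph or b_id not in graph:
        raise KeyError("both endpoints must be nodes of the candidate graph")
    if max_dist < 1:
        raise ValueError("max_dist must be at least 1")

    filtered = nx.subgraph_view(
        graph, filter_edge=lambda u, v: graph[u][v]["score"] >= min_score
    )
    best: TransformationPath | None = None
    for nodes in nx.all_simple_paths(filtered, a_id, b_id, cutoff=max_dist):
        cand = _evaluate(graph, nodes)
        if best is None or _path_rank(cand) < _path_rank(best):
            best = cand
    if best is not None:
        return best

    # best-effort fallback: maximize the worst link ignoring min_score
    fallback: TransformationPath | None = None
    for nodes in nx.all_simple_paths(graph, a_id, b_id, cutoff=max_dist):
        cand = _evaluate(graph, nodes)
        key = (-cand.worst_link, cand.length, -cand.score.value, cand.node_ids)
        if fallback is None or key < (
            -fallback.worst_link,
            fallback.length,
            -fallback.score.value,
            fallback.node_ids,
        ):
            fallback = cand
    if fallback is not None:
        fallback = TransformationPath(
            node_ids=fallback.node_ids,
            edge_scores=fallback.edge_scores,
            score=fallback.score,
            fallback=True,
        )
    raise PathNotFoundError(
        f"no simple path {a_id} -> {b_id} with all link scores >= {min_score} "
        f"within {max_dist} edges",
        fallback=fallback,
    )


def _path_rank(p: TransformationPath):
    """Sort key: higher score, then shorter, then better worst link, then ids."""
    return (-p.score.value, p.length, -p.worst_link, p.node_ids)


def path_stats(path: TransformationPath) -> tuple[float, int, float]:
    """(worst link score, path length, path score) summary of a path."""
    return (path.worst_link, path.length, path.score.value)


__all__ = [
    "TransformationPath",
    "PathNotFoundError",
    "candidate_graph",
    "find_optimal_path",
    "path_stats",
]
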