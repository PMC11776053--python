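"""Link and path scores.

The link score of an edge between compounds A and B is

    S_e = exp(-beta * (N_A + N_B - 2 * N_MCS))

where N_A, N_B and N_MCS are heavy-atom counts of the two compounds and of
their (mismatch-tolerant) MCS; the exponent counts the atoms inserted or
deleted by the perturbation.  S_e lies in (0, 1] and is 1 exactly when the
compounds are identical.  beta defaults to 0.1, the Lomap default.

The score of a path P is the harmonic mean of the squared link scores of
its edges divided by the path length, which reduces to

    S_P = 1 / sum_e (1 / S_e^2).

Higher is better; appending an edge to a path strictly lowers its score, so
the path score trades transformation difficulty against path length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .chemgraph import Molecule, compute_mcs
from .generation import CompoundRecord

DEFAULT_BETA = 0.1


@dataclass(frozen=True)
class LinkScore:
    value: float
    beta: float
    n_a: int
    n_b: int
    n_mcs: int
    timed_out: bool = False

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class PathScore:
    value: float
    edge_scores: tuple[float, ...]
    length: int

    def __float__(self) -> float:
        return self.value


def link_score(
    a: Molecule,
    b: Molecule,
    beta: float = DEFAULT_BETA,
    *,
    timeout: int = 60,
) -> LinkScore:
    """Similarity-derived difficulty score for perturbing ``a`` into ``b``."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    mcs = compute_mcs(a, b, allow_element_mismatch=True, timeout=timeout)
    delta = a.num_heavy_atoms + b.num_heavy_atoms - 2 * mcs.n_mcs
    return LinkScore(
        value=math.exp(-beta * delta),
        beta=beta,
        n_a=a.num_heavy_atoms,
        n_b=b.num_heavy_atoms,
        n_mcs=mcs.n_mcs,
        timed_out=mcs.timed_out,
    )


def path_score(edge_scores: Sequence[float | LinkScore]) -> PathScore:
    """Score of a path from its per-edge link scores (must be non-empty)."""
    values = tuple(float(s) for s in edge_scores)
    if not values:
        raise ValueError("a path must contain at least one edge")
    if any(not (0.0 < v <= 1.0) for v in values):
        raise ValueError("link scores must lie in (0, 1]")
    return PathScore(
        value=1.0 / sum(1.0 / v**2 for v in values),
        edge_scores=values,
        length=len(values),
    )


def score_matrix(
    compounds: Sequence[CompoundRecord],
    beta: float = DEFAULT_BETA,
    *,
    timeout: int = 60,
) -> pd.DataFrame:
    """Symmetric all-pairs link-score matrix with unit diagonal.

    Indexed by compound id; the quadratic MCS cost makes this the dominant
    expense for large candidate sets, so the matrix is computed once and
    reused by path search and map construction.
    """
    if len(compounds) < 2:
        raise ValueError("need at least two compounds for a score matrix")
    ids = [rec.id for rec in compounds]
    if len(set(ids)) != len(ids):
        raise ValueError("compound ids must be unique")
    mat = pd.DataFrame(1.0, index=ids, columns=ids, dtype=float)
    for i, ri in enumerate(compounds):
        for rj in compounds[i + 1 :]:
            s = link_score(ri.mol, rj.mol, beta, timeout=timeout).value
            mat.loc[ri.id, rj.id] = s
            mat.loc[rj.id, ri.id] = s
    return mat


__all__ = ["LinkScore", "PathScore", "link_score", "path_score", "score_matrix",
           "DEFAULT_BETA"]
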