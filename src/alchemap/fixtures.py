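"""Deterministic toy molecules and scored graphs for tests and examples.

The congeneric-series generator grafts small substituents onto a shared
aromatic scaffold, emulating a lead-optimization series, and can include one
"distant" member whose scaffold carries extra fused rings — the kind of
multi-ring insertion that drives a pairwise link score below 0.4
(inserting/deleting >= 10 heavy atoms at beta = 0.1 gives exp(-1) ~ 0.368)
and therefore forces intermediate injection.  Everything is constructed
programmatically; no data files are required.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import networkx as nx
from rdkit import Chem

from .chemgraph import Molecule
from .generation import CompoundRecord


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a toy congeneric series.

    ``scaffold`` is the shared core; each substituent SMILES fragment is
    attached through a single bond at the scaffold's first aromatic CH.  The
    distant member replaces the scaffold by ``distant_smiles`` (default:
    the scaffold with two extra linearly fused benzo rings).
    """

    scaffold: str = "c1ccccc1"
    substituents: tuple[str, ...] = ("C", "O", "Cl", "N", "CC", "OC")
    include_distant: bool = True
    distant_smiles: str = "c1ccc2cc3ccccc3cc2c1"  # anthracene


def _graft(scaffold: Molecule, fragment_smiles: str) -> Molecule:
    """Attach a fragment to the scaffold's lowest-index aromatic CH."""
    frag = Chem.MolFromSmiles(fragment_smiles)
    if frag is None:
        raise ValueError(f"invalid substituent fragment: {fragment_smiles!r}")
    combined = Chem.RWMol(Chem.CombineMols(scaffold.rdmol, frag))
    anchor = None
    for atom in scaffold.rdmol.GetAtoms():
        if atom.GetIsAromatic() and atom.GetTotalNumHs() > 0:
            anchor = atom.GetIdx()
            break
    if anchor is None:
        raise ValueError("scaffold has no aromatic CH to substitute")
    combined.AddBond(
        anchor, scaffold.rdmol.GetNumAtoms(), Chem.BondType.SINGLE
    )
    mol = combined.GetMol()
    Chem.SanitizeMol(mol)
    return Molecule.from_rdmol(mol)


def make_congeneric_series(spec: FixtureSpec = FixtureSpec()) -> list[CompoundRecord]:
    """Build the deterministic toy series described by ``spec``.

    All members parse, are single fragments, and share net charge 0; member
    ids are ``M1``, ``M2``, ... in recipe order.
    """
    scaffold = Molecule.from_smiles(spec.scaffold)
    mols: list[Molecule] = [scaffold]
    for frag in spec.substituents:
        mols.append(_graft(scaffold, frag))
    if spec.include_distant:
        mols.append(Molecule.from_smiles(spec.distant_smiles))
    if any(m.net_charge != 0 for m in mols):
        raise ValueError("fixture series members must be neutral")
    if len({m.canonical_key for m in mols}) != len(mols):
        raise ValueError("fixture recipe produced duplicate members")
    return [
        CompoundRecord(id=f"M{i + 1}", mol=mol, role="series_member")
        for i, mol in enumerate(mols)
    ]


def make_scored_graph(
    n_nodes: int | None = None,
    edge_score_table: dict[tuple[str, str], float] | None = None,
    *,
    seed: int | None = None,
    extra_edge_prob: float = 0.35,
) -> nx.Graph:
    """Abstract scored graph for pure graph-algorithm tests.

    Either pass an explicit ``edge_score_table`` mapping node pairs to link
    scores, or a node count plus ``seed`` for a reproducible random
    connected graph (random spanning tree plus extra edges, scores uniform
    in (0.05, 1]).
    """
    g = nx.Graph()
    if edge_score_table is not None:
        for (u, v), s in edge_score_table.items():
            if not 0.0 < s <= 1.0:
                raise ValueError(f"score for {u}-{v} must lie in (0, 1], got {s}")
            g.add_edge(u, v, score=float(s))
        return g
    if n_nodes is None or n_nodes < 2:
        raise ValueError("need n_nodes >= 2 or an explicit edge score table")
    rng = random.Random(seed)
    nodes = [f"n{i}" for i in range(n_nodes)]
    g.add_nodes_from(nodes)
    shuffled = nodes[:]
    rng.shuffle(shuffled)
    for i in range(1, n_nodes):  # random spanning tree keeps it connected
        j = rng.randrange(i)
        g.add_edge(shuffled[i], shuffled[j], score=round(rng.uniform(0.05, 1.0), 3))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            u, v = nodes[i], nodes[j]
            if not g.has_edge(u, v) and rng.random() < extra_edge_prob:
                g.add_edge(u, v, score=round(rng.uniform(0.05, 1.0), 3))
    return g


__all__ = ["FixtureSpec", "make_congeneric_series", "make_scored_graph"]
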