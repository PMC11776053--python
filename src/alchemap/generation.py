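"""Exhaustive, bidirectional enumeration of alchemical intermediates.

Given two input ligands A and B with the same net charge, candidates are
generated by repeatedly applying single graph edits that bring the current
compound closer to the common-core frame shared with the other ligand:

* ``a`` — mutate a core atom whose element/charge differs from its mapped
  counterpart in the target,
* ``b`` — delete one acyclic atom outside the core,
* ``c`` — delete a ring branch outside the core, capping with hydrogen,
* ``d`` — delete a ring branch outside the core, capping with a methyl,
* ``e`` — delete the non-core portion of a fused ring system.

Edits are applied through a LIFO compound pool with global canonical-key
deduplication until the pool is empty; generation is run from A toward B's
frame and again from B toward A's frame, and candidates whose net charge
differs from the inputs' shared charge are discarded.  Every edit strictly
reduces the number of atoms that do not yet match the target frame, so the
closure terminates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from rdkit import Chem

from .chemgraph import MCSMapping, Molecule, compute_mcs

logger = logging.getLogger(__name__)

PROCEDURES = ("a", "b", "c", "d", "e")

# safety caps for combinatorial inputs
MAX_POOL_POPS = 50_000
MAX_CANDIDATES_PER_DIRECTION = 10_000


class ChargeMismatchError(ValueError):
    """Input ligands must carry the same net charge."""


class GenerationOverflowError(RuntimeError):
    """A safety cap on the compound pool was exceeded."""


@dataclass
class CompoundRecord:
    """A molecule plus its role and generation provenance.

    ``provenance`` lists ``(procedure label, parent id)`` steps; it is empty
    for input ligands and series members and non-empty for intermediates.
    """

    id: str
    mol: Molecule
    role: str  # input_A | input_B | intermediate | series_member
    provenance: tuple[tuple[str, str], ...] = ()
    direction: str = "none"  # from_A | from_B | none

    @property
    def key(self) -> str:
        return self.mol.canonical_key


@dataclass
class GenerationResult:
    """Deduplicated candidate set from bidirectional generation."""

    candidates: dict[str, CompoundRecord]  # canonical_key -> record
    mcs_ab: MCSMapping
    stats: dict[str, int]
    a_id: str = "A"
    b_id: str = "B"

    def records(self) -> list[CompoundRecord]:
        return list(self.candidates.values())

    def by_id(self) -> dict[str, CompoundRecord]:
        return {rec.id: rec for rec in self.candidates.values()}


# ---------------------------------------------------------------------------
# single-edit enumeration
# ---------------------------------------------------------------------------


def _sanitized(rw: Chem.RWMol) -> Molecule | None:
    """Sanitize an edited molecule; edits yielding invalid chemistry are
    silently discarded (returns None)."""
    try:
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        if len(Chem.GetMolFrags(mol)) != 1:
            return None
        return Molecule.from_rdmol(mol)
    except Exception:
        return None


def _remove_atoms(
    rdmol: Chem.Mol, doomed: set[int]
) -> tuple[Chem.RWMol, dict[int, int]]:
    """Remove atoms and return the survivor old->new index map."""
    rw = Chem.RWMol(rdmol)
    for idx in sorted(doomed, reverse=True):
        rw.RemoveAtom(idx)
    survivors = [i for i in range(rdmol.GetNumAtoms()) if i not in doomed]
    idx_map = {old: new for new, old in enumerate(survivors)}
    return rw, idx_map


def _branch_atoms(rdmol: Chem.Mol, root: int, blocked: int) -> set[int]:
    """Atoms reachable from ``root`` without crossing the ``blocked`` atom."""
    seen = {root}
    stack = [root]
    while stack:
        cur = stack.pop()
        for nbr in rdmol.GetAtomWithIdx(cur).GetNeighbors():
            n = nbr.GetIdx()
            if n != blocked and n not in seen:
                seen.add(n)
                stack.append(n)
    return seen


def enumerate_edits(
    mol: Molecule, target: Molecule, mapping: dict[int, int]
) -> list[tuple[str, Molecule, dict[int, int]]]:
    """All molecules one edit away from ``mol`` toward ``target``'s frame.

    ``mapping`` sends core atom indices of ``mol`` to their counterparts in
    ``target``.  Returns ``(procedure, edited molecule, remapped core)``
    tuples; the remapped core is the same correspondence expressed in the
    edited molecule's atom indices.
    """
    rdmol = mol.rdmol
    out: list[tuple[str, Molecule, dict[int, int]]] = []

    # --- procedure a: mutate mismatched core atoms -------------------------
    for i, j in sorted(mapping.items()):
        src = rdmol.GetAtomWithIdx(i)
        dst = target.rdmol.GetAtomWithIdx(j)
        if (src.GetAtomicNum(), src.GetFormalCharge()) == (
            dst.GetAtomicNum(),
            dst.GetFormalCharge(),
        ):
            continue
        rw = Chem.RWMol(rdmol)
        atom = rw.GetAtomWithIdx(i)
        atom.SetAtomicNum(dst.GetAtomicNum())
        atom.SetFormalCharge(dst.GetFormalCharge())
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(False)
        edited = _sanitized(rw)
        if edited is not None:
            out.append(("a", edited, dict(mapping)))

    non_core = [i for i in range(rdmol.GetNumAtoms()) if i not in mapping]
    ring_info = rdmol.GetRingInfo()

    # --- procedure b: delete one acyclic non-core atom ----------------------
    for i in non_core:
        if rdmol.GetAtomWithIdx(i).IsInRing():
            continue
        rw, idx_map = _remove_atoms(rdmol, {i})
        edited = _sanitized(rw)
        if edited is not None:
            out.append(("b", edited, {idx_map[k]: v for k, v in mapping.items()}))

    # --- procedures c/d: delete a ring-containing non-core branch ----------
    ring_atoms = {a for ring in ring_info.AtomRings() for a in ring}
    for bond in rdmol.GetBonds():
        if bond.IsInRing():
            continue
        for anchor, root in (
            (bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()),
            (bond.GetEndAtomIdx(), bond.GetBeginAtomIdx()),
        ):
            branch = _branch_atoms(rdmol, root, anchor)
            if branch & set(mapping):
                continue
            # branch must contain at least one complete ring
            if not any(set(r) <= branch for r in ring_info.AtomRings()):
                continue
            rw, idx_map = _remove_atoms(rdmol, branch)
            edited = _sanitized(rw)
            remap = {idx_map[k]: v for k, v in mapping.items()}
            if edited is not None:
                out.append(("c", edited, remap))
            # d: same deletion, capped with a methyl carbon at the anchor
            rw_d, idx_map_d = _remove_atoms(rdmol, branch)
            new_c = rw_d.AddAtom(Chem.Atom(6))
            rw_d.AddBond(idx_map_d[anchor], new_c, Chem.BondType.SINGLE)
            edited_d = _sanitized(rw_d)
            if edited_d is not None:
                out.append(
                    ("d", edited_d, {idx_map_d[k]: v for k, v in mapping.items()})
                )

    # --- procedure e: trim the non-core ring of a fused system -------------
    rings = ring_info.AtomRings()
    for ri, ring in enumerate(rings):
        ring_set = set(ring)
        fused = any(
            len(ring_set & set(other)) >= 2
            for rj, other in enumerate(rings)
            if rj != ri
        )
        if not fused:
            continue
        other_ring_atoms = {
            a for rj, other in enumerate(rings) if rj != ri for a in other
        }
        doomed = {a for a in ring if a not in mapping and a not in other_ring_atoms}
        if not doomed or doomed == ring_set:
            continue
        rw, idx_map = _remove_atoms(rdmol, doomed)
        edited = _sanitized(rw)
        if edited is not None:
            out.append(("e", edited, {idx_map[k]: v for k, v in mapping.items()}))

    return out


# ---------------------------------------------------------------------------
# compound-pool closure
# ---------------------------------------------------------------------------


def generate_directed(
    start: CompoundRecord,
    target: CompoundRecord,
    mcs: MCSMapping,
    *,
    direction: str = "from_A",
    id_prefix: str = "I",
    max_pool_pops: int = MAX_POOL_POPS,
    max_candidates: int = MAX_CANDIDATES_PER_DIRECTION,
) -> dict[str, CompoundRecord]:
    """Closure of single edits from ``start`` toward the common core.

    Implements the compound pool: the start compound is pushed, then
    compounds are popped and all applicable single-edit products generated;
    only products not seen before (by canonical key) are pushed back, until
    the pool is empty.  Products whose net charge differs from the start's
    are excluded from further processing.
    """
    charge = start.mol.net_charge
    mapping = dict(mcs.pairs)

    results: dict[str, CompoundRecord] = {start.key: start}
    visited = {start.key}
    pool: list[tuple[Molecule, dict[int, int], CompoundRecord]] = [
        (start.mol, mapping, start)
    ]
    pops = 0
    counter = 0
    while pool:
        pops += 1
        if pops > max_pool_pops:
            raise GenerationOverflowError(
                f"compound pool exceeded {max_pool_pops} pops "
                f"({start.id} -> {target.id}); inputs too combinatorial"
            )
        mol, cur_map, parent = pool.pop()
        edits = enumerate_edits(mol, target.mol, cur_map)
        # deterministic expansion order regardless of RDKit internals
        edits.sort(key=lambda t: (t[0], t[1].canonical_key))
        for proc, child, child_map in edits:
            if child.canonical_key in visited:
                continue
            visited.add(child.canonical_key)
            if child.net_charge != charge:
                logger.debug(
                    "discarding charge-shifted intermediate %s", child.canonical_key
                )
                continue
            counter += 1
            if counter > max_candidates:
                raise GenerationOverflowError(
                    f"more than {max_candidates} candidates generated in one "
                    f"direction ({start.id} -> {target.id})"
                )
            rec = CompoundRecord(
                id=f"{id_prefix}{counter}",
                mol=child,
                role="intermediate",
                provenance=parent.provenance + ((proc, parent.id),),
                direction=direction,
            )
            results[child.canonical_key] = rec
            pool.append((child, child_map, rec))
    return results


def exhaustive_generate(
    ligand_a: Molecule | CompoundRecord,
    ligand_b: Molecule | CompoundRecord,
    *,
    mcs_timeout: int = 60,
    a_id: str = "A",
    b_id: str = "B",
) -> GenerationResult:
    """Bidirectional exhaustive intermediate generation between two ligands.

    Raises :class:`ChargeMismatchError` before any generation if the inputs'
    net charges differ.
    """
    rec_a = (
        ligand_a
        if isinstance(ligand_a, CompoundRecord)
        else CompoundRecord(id=a_id, mol=ligand_a, role="input_A")
    )
    rec_b = (
        ligand_b
        if isinstance(ligand_b, CompoundRecord)
        else CompoundRecord(id=b_id, mol=ligand_b, role="input_B")
    )
    if rec_a.mol.net_charge != rec_b.mol.net_charge:
        raise ChargeMismatchError(
            f"net charges differ: {rec_a.id}={rec_a.mol.net_charge:+d} e, "
            f"{rec_b.id}={rec_b.mol.net_charge:+d} e"
        )

    mcs_ab = compute_mcs(rec_a.mol, rec_b.mol, timeout=mcs_timeout)

    from_a = generate_directed(
        rec_a, rec_b, mcs_ab, direction="from_A", id_prefix=f"{a_id}_i"
    )
    from_b = generate_directed(
        rec_b, rec_a, mcs_ab.inverted(), direction="from_B", id_prefix=f"{b_id}_i"
    )

    candidates: dict[str, CompoundRecord] = {}
    candidates[rec_a.key] = rec_a
    candidates[rec_b.key] = rec_b
    stats = {p: 0 for p in PROCEDURES}
    for pool in (from_a, from_b):
        for key, rec in sorted(pool.items()):
            if key not in candidates:
                candidates[key] = rec
                stats[rec.provenance[-1][0]] += 1
    return GenerationResult(
        candidates=candidates,
        mcs_ab=mcs_ab,
        stats=stats,
        a_id=rec_a.id,
        b_id=rec_b.id,
    )


__all__ = [
    "CompoundRecord",
    "GenerationResult",
    "ChargeMismatchError",
    "GenerationOverflowError",
    "enumerate_edits",
    "generate_directed",
    "exhaustive_generate",
    "PROCEDURES",
]
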