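"""Molecular graphs, canonicalization, charge rules, and tolerant MCS.

Molecules are handled as hydrogen-suppressed RDKit graphs.  All atom counts
in this package are heavy-atom counts.  The maximum common substructure
(MCS) is computed with *incomplete atom-type matching*: two atoms may be
paired even when their elements differ, which is what makes alchemical
element mutations (e.g. a ring C -> N swap) count as a single perturbed
atom rather than a delete + insert.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import rdFMCS

logger = logging.getLogger(__name__)

# RDKit is chatty on intentionally-invalid edit products; keep stderr clean.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")


class ParseError(ValueError):
    """Raised when a structure record cannot be parsed or sanitized."""


@dataclass(frozen=True)
class Molecule:
    """A single connected, sanitized, hydrogen-suppressed molecule.

    ``canonical_key`` is the canonical isomeric SMILES; it is invariant
    under atom reordering and is used throughout the package to
    deduplicate generated intermediates.
    """

    rdmol: Chem.Mol
    canonical_key: str
    net_charge: int
    num_heavy_atoms: int

    @staticmethod
    def from_rdmol(rdmol: Chem.Mol, *, source: str = "<mol>") -> "Molecule":
        if rdmol is None:
            raise ParseError(f"could not parse structure: {source}")
        try:
            Chem.SanitizeMol(rdmol)
        except Exception as exc:  # pragma: no cover - rdkit raises many types
            raise ParseError(f"could not sanitize structure {source}: {exc}") from exc
        rdmol = Chem.RemoveHs(rdmol)
        frags = Chem.GetMolFrags(rdmol)
        if len(frags) != 1:
            raise ParseError(
                f"multi-fragment input rejected ({len(frags)} fragments): {source}"
            )
        return Molecule(
            rdmol=rdmol,
            canonical_key=Chem.MolToSmiles(rdmol),
            net_charge=Chem.GetFormalCharge(rdmol),
            num_heavy_atoms=rdmol.GetNumHeavyAtoms(),
        )

    @staticmethod
    def from_smiles(smiles: str) -> "Molecule":
        rdmol = Chem.MolFromSmiles(smiles, sanitize=False)
        if rdmol is None:
            raise ParseError(f"invalid SMILES: {smiles!r}")
        return Molecule.from_rdmol(rdmol, source=smiles)

    @staticmethod
    def from_molblock(molblock: str, *, source: str = "<sdf record>") -> "Molecule":
        rdmol = Chem.MolFromMolBlock(molblock, sanitize=False, removeHs=False)
        if rdmol is None:
            raise ParseError(f"invalid mol block: {source}")
        return Molecule.from_rdmol(rdmol, source=source)

    def to_smiles(self) -> str:
        return self.canonical_key

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Molecule) and self.canonical_key == other.canonical_key

    def __hash__(self) -> int:
        return hash(self.canonical_key)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Molecule({self.canonical_key!r})"


def parse_structure(text: str, fmt: str = "smiles") -> Molecule:
    """Parse one structure record in the named format (``smiles``/``sdf``)."""
    fmt = fmt.lower()
    if fmt in ("smiles", "smi"):
        # allow an optional whitespace-separated name column
        token = text.strip().split()[0] if text.strip() else ""
        return Molecule.from_smiles(token)
    if fmt in ("sdf", "mol", "molblock"):
        return Molecule.from_molblock(text)
    raise ValueError(f"unknown structure format: {fmt!r}")


def canonical_key(mol: Molecule) -> str:
    return mol.canonical_key


# ---------------------------------------------------------------------------
# MCS with incomplete atom-type matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MCSMapping:
    """One-to-one heavy-atom correspondence between two molecules.

    ``pairs[i] = (atom index in A, atom index in B)``; ``mismatched_pairs``
    are the pairs whose element symbols differ (tolerated element swaps).
    """

    pairs: tuple[tuple[int, int], ...]
    n_mcs: int
    mismatched_pairs: tuple[tuple[int, int], ...] = ()
    timed_out: bool = False

    def inverted(self) -> "MCSMapping":
        return MCSMapping(
            pairs=tuple((j, i) for i, j in self.pairs),
            n_mcs=self.n_mcs,
            mismatched_pairs=tuple((j, i) for i, j in self.mismatched_pairs),
            timed_out=self.timed_out,
        )


_MAX_MATCHES = 128


def _flavor_query(
    raw_query: Chem.Mol,
    ref_mol: Chem.Mol,
    ref_match: tuple[int, ...],
    allow_element_mismatch: bool,
    ring_constrained: bool,
) -> Chem.Mol:
    """Rewrite the MCS result SMARTS into an explicit matching-flavor query.

    The SMARTS RDKit emits for a tolerant MCS can still pin elements or bond
    orders seen in only one input, which breaks re-matching it into the
    other input.  This rebuilds every atom/bond query from the declared
    flavor: any element (or the reference element under strict matching),
    any bond order, with ring membership taken from the reference match when
    the ring constraint is active.
    """
    from rdkit.Chem import rdqueries

    rw = Chem.RWMol(raw_query)
    for qi in range(rw.GetNumAtoms()):
        ref_atom = ref_mol.GetAtomWithIdx(ref_match[qi])
        if allow_element_mismatch:
            qa = rdqueries.AtomNumGreaterQueryAtom(0)
        else:
            qa = rdqueries.AtomNumEqualsQueryAtom(ref_atom.GetAtomicNum())
        if ring_constrained:
            qa.ExpandQuery(
                rdqueries.IsInRingQueryAtom(negate=not ref_atom.IsInRing()),
                Chem.CompositeQueryType.COMPOSITE_AND,
            )
        rw.ReplaceAtom(qi, qa)
    for bond in raw_query.GetBonds():
        ref_bond = ref_mol.GetBondBetweenAtoms(
            ref_match[bond.GetBeginAtomIdx()], ref_match[bond.GetEndAtomIdx()]
        )
        if ring_constrained:
            smarts = "~;@" if ref_bond.IsInRing() else "~;!@"
        else:
            smarts = "~"
        rw.ReplaceBond(bond.GetIdx(), Chem.BondFromSmarts(smarts))
    return rw.GetMol()


def _find_mcs_query(
    a: Chem.Mol, b: Chem.Mol, allow_element_mismatch: bool, timeout: int,
    ring_matches_ring_only: bool,
):
    return rdFMCS.FindMCS(
        [a, b],
        atomCompare=(
            rdFMCS.AtomCompare.CompareAny
            if allow_element_mismatch
            else rdFMCS.AtomCompare.CompareElements
        ),
        bondCompare=rdFMCS.BondCompare.CompareAny,
        maximizeBonds=False,
        ringMatchesRingOnly=ring_matches_ring_only,
        completeRingsOnly=False,
        matchValences=False,
        timeout=max(1, int(timeout)),
    )


def _single_atom_anchor(
    a: Molecule, b: Molecule, allow_element_mismatch: bool, canceled: bool
) -> MCSMapping:
    """Degenerate one-atom mapping used when no bonded common substructure
    respects the ring-matching rule (e.g. a fully acyclic molecule against a
    fully cyclic one).  A single atom carries no bonds, so the ring-bond
    constraint is vacuous; the pair is chosen deterministically by canonical
    atom rank (lowest ranks, matching elements preferred, then required
    under strict matching)."""
    rank_a = list(Chem.CanonicalRankAtoms(a.rdmol, breakTies=True))
    rank_b = list(Chem.CanonicalRankAtoms(b.rdmol, breakTies=True))
    best = None
    for atom_a in a.rdmol.GetAtoms():
        for atom_b in b.rdmol.GetAtoms():
            mismatch = atom_a.GetSymbol() != atom_b.GetSymbol()
            if mismatch and not allow_element_mismatch:
                continue
            key = (mismatch, rank_a[atom_a.GetIdx()], rank_b[atom_b.GetIdx()])
            if best is None or key < best[0]:
                best = (key, atom_a.GetIdx(), atom_b.GetIdx(), mismatch)
    if best is None:
        return MCSMapping(pairs=(), n_mcs=0, timed_out=canceled)
    _, i, j, mismatch = best
    return MCSMapping(
        pairs=((i, j),),
        n_mcs=1,
        mismatched_pairs=((i, j),) if mismatch else (),
        timed_out=canceled,
    )


def compute_mcs(
    a: Molecule,
    b: Molecule,
    allow_element_mismatch: bool = True,
    timeout: int = 60,
) -> MCSMapping:
    """Maximum connected common substructure of ``a`` and ``b``.

    Atom compatibility is by connectivity only when ``allow_element_mismatch``
    is set (mismatching elements are recorded); ring bonds may only map to
    ring bonds.  When the ring-constrained search finds no common atoms at
    all (e.g. one molecule is acyclic and the other fully cyclic) the search
    is retried without the ring constraint so that a bondless single-atom
    anchor can still be mapped.

    Among equally large mappings the one with the fewest element mismatches
    is chosen, then the lexicographically smallest pair list under canonical
    atom ranks, so results are independent of input atom order.
    """
    matches_a = matches_b = ()
    canceled = False
    result = _find_mcs_query(a.rdmol, b.rdmol, allow_element_mismatch, timeout, True)
    canceled = bool(result.canceled)
    if canceled:
        logger.warning(
            "MCS search timed out after %ss for %s vs %s; using best found",
            timeout, a.canonical_key, b.canonical_key,
        )
    if result.numAtoms > 0:
        raw = Chem.MolFromSmarts(result.smartsString)
        ref_matches = a.rdmol.GetSubstructMatches(raw, uniquify=False, maxMatches=1)
        ref_mol = a.rdmol
        if not ref_matches:
            ref_matches = b.rdmol.GetSubstructMatches(raw, uniquify=False, maxMatches=1)
            ref_mol = b.rdmol
        if ref_matches:
            query = _flavor_query(
                raw, ref_mol, ref_matches[0], allow_element_mismatch, True
            )
            matches_a = a.rdmol.GetSubstructMatches(
                query, uniquify=False, maxMatches=_MAX_MATCHES
            )
            matches_b = b.rdmol.GetSubstructMatches(
                query, uniquify=False, maxMatches=_MAX_MATCHES
            )
    if not matches_a or not matches_b:
        return _single_atom_anchor(a, b, allow_element_mismatch, canceled)

    rank_a = list(Chem.CanonicalRankAtoms(a.rdmol, breakTies=True))
    rank_b = list(Chem.CanonicalRankAtoms(b.rdmol, breakTies=True))
    sym_a = [at.GetSymbol() for at in a.rdmol.GetAtoms()]
    sym_b = [at.GetSymbol() for at in b.rdmol.GetAtoms()]

    best = None
    for ma in matches_a:
        for mb in matches_b:
            mismatches = sum(1 for i, j in zip(ma, mb) if sym_a[i] != sym_b[j])
            rank_key = tuple(sorted((rank_a[i], rank_b[j]) for i, j in zip(ma, mb)))
            key = (mismatches, rank_key)
            if best is None or key < best[0]:
                best = (key, ma, mb)
    _, ma, mb = best
    pairs = tuple(sorted(zip(ma, mb)))
    mismatched = tuple((i, j) for i, j in pairs if sym_a[i] != sym_b[j])
    return MCSMapping(
        pairs=pairs,
        n_mcs=len(pairs),
        mismatched_pairs=mismatched,
        timed_out=canceled,
    )


# ---------------------------------------------------------------------------
# Deterministic formal-charge assignment
# ---------------------------------------------------------------------------

# Rule table applied at a nominal pH of 7.4: (name, SMARTS, pattern atom
# index to charge, formal charge to set).  Rules only touch atoms that are
# currently neutral; explicit charges present in the input are preserved.
DEFAULT_CHARGE_RULES: tuple[tuple[str, str, int, int], ...] = (
    ("carboxylic acid -> carboxylate", "[CX3](=[OX1])[OX2H1]", 2, -1),
    ("sulfonic acid -> sulfonate", "[SX4](=[OX1])(=[OX1])[OX2H1]", 3, -1),
    ("phosphonic acid -> phosphonate", "[PX4](=[OX1])([OX2H1])[OX2H1]", 2, -1),
    (
        "aliphatic amine -> ammonium",
        "[NX3;H2,H1,H0;+0;!$([N]~[!#6;!#1]);!$([N]c);!$([N]C=[O,S,N])]",
        0,
        +1,
    ),
)


def assign_net_charge(
    mol: Molecule,
    rules: Sequence[tuple[str, str, int, int]] = DEFAULT_CHARGE_RULES,
) -> Molecule:
    """Apply the fixed protonation-state rule table and return a new molecule.

    Atoms that already carry an explicit formal charge are left untouched;
    rules fire only on rule-matching neutral groups.
    """
    rw = Chem.RWMol(mol.rdmol)
    changed = False
    for name, smarts, target_idx, charge in rules:
        patt = Chem.MolFromSmarts(smarts)
        for match in rw.GetMol().GetSubstructMatches(patt):
            atom = rw.GetAtomWithIdx(match[target_idx])
            if atom.GetFormalCharge() != 0:
                continue
            atom.SetFormalCharge(charge)
            # let sanitization recompute implicit hydrogens for the new state
            atom.SetNumExplicitHs(0)
            atom.SetNoImplicit(False)
            changed = True
            logger.debug("charge rule fired: %s", name)
    if not changed:
        return mol
    return Molecule.from_rdmol(rw.GetMol(), source=mol.canonical_key)


__all__ = [
    "Molecule",
    "MCSMapping",
    "ParseError",
    "parse_structure",
    "canonical_key",
    "compute_mcs",
    "assign_net_charge",
    "DEFAULT_CHARGE_RULES",
]
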