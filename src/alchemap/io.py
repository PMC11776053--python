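"""Reading and writing of structures, maps, and reports.

Structures: SMILES lists (one record per line, optional whitespace-separated
name) and multi-record SDF V2000.  Maps: GraphML (node id, SMILES, role;
edge score and optimal flag) and flat CSV edge lists; both round-trip
through the readers here.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import networkx as nx
import pandas as pd
from rdkit import Chem

from .chemgraph import Molecule, ParseError
from .generation import CompoundRecord
from .mapbuild import PerturbationMap, _norm


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------


def read_smiles_file(path: str | Path, role: str = "series_member") -> list[CompoundRecord]:
    records: list[CompoundRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        try:
            mol = Molecule.from_smiles(parts[0])
        except ParseError as exc:
            raise ParseError(f"{path}, line {lineno}: {exc}") from exc
        name = parts[1].strip() if len(parts) > 1 else f"M{len(records) + 1}"
        records.append(CompoundRecord(id=name, mol=mol, role=role))
    return records


def read_sdf(path: str | Path, role: str = "series_member") -> list[CompoundRecord]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    records: list[CompoundRecord] = []
    for i, rdmol in enumerate(supplier, start=1):
        if rdmol is None:
            raise ParseError(f"{path}: record {i} could not be parsed")
        name = rdmol.GetProp("_Name").strip() if rdmol.HasProp("_Name") else ""
        mol = Molecule.from_rdmol(rdmol, source=f"{path} record {i} ({name or 'unnamed'})")
        records.append(CompoundRecord(id=name or f"M{i}", mol=mol, role=role))
    return records


def read_structures(path: str | Path, role: str = "series_member") -> list[CompoundRecord]:
    """Dispatch on file extension (.smi/.smiles/.txt vs .sdf/.mol)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".sdf", ".mol"):
        return read_sdf(path, role)
    return read_smiles_file(path, role)


def write_smiles_file(records: list[CompoundRecord], path: str | Path) -> None:
    lines = [f"{rec.mol.canonical_key}\t{rec.id}" for rec in records]
    Path(path).write_text("\n".join(lines) + "\n")


def write_sdf(records: list[CompoundRecord], path: str | Path) -> None:
    """Multi-record SDF with role/provenance/direction in record properties."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    try:
        for rec in records:
            rdmol = Chem.Mol(rec.mol.rdmol)
            rdmol.SetProp("_Name", rec.id)
            rdmol.SetProp("role", rec.role)
            rdmol.SetProp("direction", rec.direction)
            if rec.provenance:
                rdmol.SetProp(
                    "provenance",
                    ";".join(f"{proc}:{parent}" for proc, parent in rec.provenance),
                )
            writer.write(rdmol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# maps
# ---------------------------------------------------------------------------


def write_graphml(pmap: PerturbationMap, path: str | Path) -> None:
    g = nx.Graph()
    g.graph["a_id"] = pmap.endpoints[0] or ""
    g.graph["b_id"] = pmap.endpoints[1] or ""
    for key, value in sorted(pmap.params.items()):
        g.graph[f"param_{key}"] = value
    for node in pmap.graph.nodes:
        data = pmap.graph.nodes[node]
        g.add_node(node, smiles=data.get("smiles", ""), role=data.get("role", ""))
    for u, v, data in pmap.graph.edges(data=True):
        g.add_edge(
            u,
            v,
            score=float(data["score"]),
            optimal=bool(data.get("optimal", False)),
        )
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> PerturbationMap:
    g = nx.read_graphml(str(path))
    graph = nx.Graph()
    for node, data in g.nodes(data=True):
        graph.add_node(node, smiles=data.get("smiles", ""), role=data.get("role", ""))
    optimal: set = set()
    for u, v, data in g.edges(data=True):
        graph.add_edge(u, v, score=float(data["score"]), optimal=bool(data.get("optimal")))
        if data.get("optimal"):
            optimal.add(_norm(u, v))
    params = {
        key[len("param_"):]: value
        for key, value in g.graph.items()
        if key.startswith("param_")
    }
    a_id = g.graph.get("a_id") or None
    b_id = g.graph.get("b_id") or None
    return PerturbationMap(
        graph=graph,
        endpoints=(a_id, b_id),
        optimal_links=frozenset(optimal),
        params=params,
    )


def write_edge_csv(pmap: PerturbationMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node_a", "node_b", "score", "optimal"])
        for u, v in sorted(_norm(x, y) for x, y in pmap.graph.edges):
            data = pmap.graph[u][v]
            writer.writerow([u, v, f"{data['score']:.6f}", int(bool(data.get("optimal")))])


def read_edge_csv(path: str | Path) -> nx.Graph:
    graph = nx.Graph()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            graph.add_edge(
                row["node_a"],
                row["node_b"],
                score=float(row["score"]),
                optimal=bool(int(row["optimal"])),
            )
    return graph


def write_score_matrix_csv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, float_format="%.6f")


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


__all__ = [
    "read_smiles_file",
    "read_sdf",
    "read_structures",
    "write_smiles_file",
    "write_sdf",
    "write_graphml",
    "read_graphml",
    "write_edge_csv",
    "read_edge_csv",
    "write_score_matrix_csv",
    "write_json_report",
]
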