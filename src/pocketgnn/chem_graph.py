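"""SMILES strings to labeled molecular graphs.

A compound is represented as an undirected graph over its heavy atoms.
Vertex labels are element symbols with the aromatic flag folded in (an
aromatic carbon is a different label from an aliphatic one); edge labels
are the bond order class (single / double / triple / aromatic).
Hydrogens are implicit and omitted.  Multi-component SMILES (containing
a dot) cannot yield a single connected graph and are excluded from any
dataset rather than parsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: suffix appended to the element symbol of an aromatic atom
AROMATIC_TAG = "*"

_BOND_TYPES = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


class SmilesParseError(ValueError):
    """Raised when RDKit cannot parse a SMILES string or a bond order is
    outside the single/double/triple/aromatic classes."""


@dataclass(frozen=True)
class ExclusionMark:
    """Record of a compound excluded from a dataset (never an error).

    The only exclusion rule is the dot rule: a SMILES encoding several
    disconnected components is dropped because no single graph exists.
    """

    reason: str
    smiles: str = ""


@dataclass
class MolecularGraph:
    """Labeled undirected heavy-atom graph of one connected molecule.

    ``vertex_labels[i]`` is the atom-type label of vertex ``i``;
    ``edges`` holds each bond once as ``(i, j, bond_type)`` with
    ``i < j``.
    """

    vertex_labels: list[str]
    edges: list[tuple[int, int, str]]
    source_smiles: str = ""

    def __post_init__(self) -> None:
        n = len(self.vertex_labels)
        if n < 1:
            raise ValueError("molecular graph needs at least one vertex")
        seen: set[tuple[int, int]] = set()
        for i, j, _ in self.edges:
            if not (0 <= i < j < n):
                raise ValueError(f"bad edge ({i}, {j}) for {n} vertices")
            if (i, j) in seen:
                raise ValueError(f"duplicate edge ({i}, {j})")
            seen.add((i, j))

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_labels)


def atom_label(symbol: str, aromatic: bool) -> str:
    return symbol + AROMATIC_TAG if aromatic else symbol


def parse_smiles(smiles: str) -> MolecularGraph | ExclusionMark:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Returns an :class:`ExclusionMark` for multi-component (dot) SMILES.

    Raises
    ------
    SmilesParseError
        If the string is empty or chemically unparsable.  This is kept
        distinct from exclusion: a bad record is an error, a dotted
        record is a documented dataset filter.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) > 1:
        return ExclusionMark(reason="dot-disconnected", smiles=smiles)

    labels = [atom_label(a.GetSymbol(), a.GetIsAromatic()) for a in mol.GetAtoms()]
    edges: list[tuple[int, int, str]] = []
    for bond in mol.GetBonds():
        try:
            btype = _BOND_TYPES[bond.GetBondType()]
        except KeyError:
            raise SmilesParseError(
                f"unsupported bond type {bond.GetBondType()} in {smiles!r}"
            ) from None
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i > j:
            i, j = j, i
        edges.append((i, j, btype))
    edges.sort()
    return MolecularGraph(vertex_labels=labels, edges=edges, source_smiles=smiles)


def write_edge_list(graph: MolecularGraph) -> str:
    """Debug export: vertex block then tab-separated edge lines."""
    lines = [f"#molgraph v1 n={graph.n_vertices} m={len(graph.edges)}"]
    for idx, lab in enumerate(graph.vertex_labels):
        lines.append(f"v\t{idx}\t{lab}")
    for i, j, t in graph.edges:
        lines.append(f"{i}\t{j}\t{t}")
    return "\n".join(lines) + "\n"
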