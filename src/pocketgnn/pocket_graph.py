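"""Binding-pocket residue graphs from PDB protein–ligand complexes.

The pocket of a target is defined by the residues in contact with its
co-crystallized ligand.  Each contact residue becomes one vertex,
labeled by its amino-acid type (20 standard types, one-hot encoded);
every residue pair whose Cα–Cα distance falls in one of five bins

    I: [1.0, 4.8)   II: [4.8, 7.0)   III: [7.0, 9.2)
    IV: [9.2, 11.4)  V: [11.4, 13.6)  (Å, half-open)

is connected by an edge of that class.  Coarse distance classes, rather
than raw distances, make the representation tolerant to small pocket
flexibility.  Contact identification uses an explicit heavy-atom
distance criterion (default 4.5 Å) so the preprocessing is fully
reproducible.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser

#: the 20 standard amino acids, alphabetical by three-letter code;
#: position in this tuple is the one-hot index (ALA=0 ... VAL=19)
STANDARD_AA3 = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
_AA3_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA3)}

#: edge classes in bin order, with half-open [lo, hi) boundaries in Å
EDGE_CLASSES = ("I", "II", "III", "IV", "V")
BIN_EDGES = (1.0, 4.8, 7.0, 9.2, 11.4, 13.6)

DEFAULT_CONTACT_CUTOFF = 4.5  # Å, min heavy-atom separation defining a contact


class PocketError(ValueError):
    """Structure-level failure: missing ligand, no ATOM records, empty pocket."""


class NonStandardResidue(ValueError):
    """Residue type outside the 20 standard amino acids."""


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    aa3: str
    ca_coord: np.ndarray
    heavy_atom_coords: list[np.ndarray] = field(default_factory=list)
    insertion_code: str = " "

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)


@dataclass
class PocketGraph:
    """Residue-interaction graph of one binding pocket.

    ``edges`` holds each residue pair once as ``(i, j, edge_class)``
    with ``i < j``; ``vertex_onehots`` is an (n, 20) indicator matrix.
    """

    residues: list[Residue]
    vertex_onehots: np.ndarray
    edges: list[tuple[int, int, str]]

    @property
    def vertex_labels(self) -> list[str]:
        """Amino-acid labels, the symbolic form of the one-hot rows."""
        return [r.aa3 for r in self.residues]

    @property
    def n_vertices(self) -> int:
        return len(self.residues)


def bin_ca_distance(d: float) -> str | None:
    """Map a Cα–Cα distance (Å) to an edge class, or None outside all bins.

    The printed bins share endpoints, so half-open [lo, hi) intervals
    are used: 4.8 Å belongs to class II, not I.  Distances below 1.0 Å
    (steric clashes, a data-quality issue) yield no edge.
    """
    if d < 0:
        raise ValueError(f"negative distance: {d}")
    for k in range(5):
        if BIN_EDGES[k] <= d < BIN_EDGES[k + 1]:
            return EDGE_CLASSES[k]
    return None


def residue_one_hot(aa3: str) -> np.ndarray:
    """20-dimensional indicator vector for a standard amino-acid code."""
    try:
        idx = _AA3_INDEX[aa3]
    except KeyError:
        raise NonStandardResidue(f"not a standard amino acid: {aa3!r}") from None
    v = np.zeros(20)
    v[idx] = 1.0
    return v


def _first_altloc_atoms(residue) -> list:
    atoms = []
    for atom in residue.get_unpacked_list():
        alt = atom.get_altloc()
        if alt not in (" ", "A"):
            continue  # keep the first alternate location only
        atoms.append(atom)
    return atoms


def parse_pdb_complex(
    pdb_text: str, ligand_code: str
) -> tuple[list[Residue], list[np.ndarray]]:
    """Split a PDB complex into protein residues and ligand heavy atoms.

    Protein residues are grouped by (chain, sequence number, insertion
    code) from ATOM records; residues lacking a Cα are dropped with a
    warning.  Ligand atoms are the heavy atoms of the first HETATM
    residue whose code equals ``ligand_code``; waters are never a ligand.
    """
    if ligand_code.strip().upper() == "HOH":
        raise PocketError("water (HOH) cannot be the ligand")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("complex", io.StringIO(pdb_text))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise PocketError("no models in PDB text") from None

    protein: list[Residue] = []
    ligand_atoms: list[np.ndarray] = []
    ligand_found = False
    for chain in model:
        for res in chain:
            hetfield, seqnum, icode = res.get_id()
            atoms = _first_altloc_atoms(res)
            heavy = [a for a in atoms if a.element != "H"]
            if hetfield == " ":
                ca = next((a for a in heavy if a.get_name() == "CA"), None)
                if ca is None:
                    warnings.warn(
                        f"residue {chain.id}/{seqnum}{icode.strip()} "
                        f"({res.get_resname()}) has no CA atom; dropped"
                    )
                    continue
                protein.append(
                    Residue(
                        chain_id=chain.id,
                        seq_number=seqnum,
                        aa3=res.get_resname().strip(),
                        ca_coord=np.asarray(ca.get_coord(), dtype=float),
                        heavy_atom_coords=[
                            np.asarray(a.get_coord(), dtype=float) for a in heavy
                        ],
                        insertion_code=icode,
                    )
                )
            elif res.get_resname().strip() == ligand_code.strip() and not ligand_found:
                # first matching copy if the ligand occurs multiple times
                if res.get_resname().strip() == "HOH":
                    continue
                ligand_atoms = [
                    np.asarray(a.get_coord(), dtype=float) for a in heavy
                ]
                ligand_found = True

    if not protein:
        raise PocketError("no ATOM records (protein residues) found")
    if not ligand_found:
        raise PocketError(f"ligand code {ligand_code!r} not found among HETATM records")
    return protein, ligand_atoms


def extract_contact_residues(
    protein_residues: list[Residue],
    ligand_atoms: list[np.ndarray],
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list[Residue]:
    """Residues with any heavy atom within ``contact_cutoff`` Å of the ligand.

    Output preserves the original sequence order.  An empty result is
    valid but suspicious (ligand far from the protein) and warns.
    """
    if contact_cutoff <= 0:
        raise ValueError("contact_cutoff must be positive")
    if not ligand_atoms:
        raise PocketError("empty ligand: no heavy atoms to measure contacts against")
    lig = np.asarray(ligand_atoms)
    contacts = []
    for res in protein_residues:
        coords = np.asarray(res.heavy_atom_coords)
        dmin = np.sqrt(
            ((coords[:, None, :] - lig[None, :, :]) ** 2).sum(axis=2)
        ).min()
        if dmin <= contact_cutoff:
            contacts.append(res)
    if not contacts:
        warnings.warn(
            f"no residues within {contact_cutoff} Å of the ligand; empty pocket"
        )
    return contacts


def build_pocket_graph(contact_residues: list[Residue]) -> PocketGraph:
    """Assemble the residue-interaction graph over admissible residues.

    Residues with non-standard types (e.g. MSE) are dropped with a
    warning — the 20-type one-hot admits nothing else.  Edges are
    derived purely from Cα–Cα distances through :func:`bin_ca_distance`;
    both bonded (sequence-adjacent) and non-bonded interactions are
    captured by the same distance classes.
    """
    admitted = []
    for res in contact_residues:
        if res.aa3 not in _AA3_INDEX:
            warnings.warn(f"non-standard residue {res.aa3} at {res.key}; dropped")
            continue
        admitted.append(res)
    if not admitted:
        raise PocketError("empty pocket: no admissible contact residues")

    onehots = np.stack([residue_one_hot(r.aa3) for r in admitted])
    cas = np.stack([r.ca_coord for r in admitted])
    edges: list[tuple[int, int, str]] = []
    n = len(admitted)
    for i in range(n):
        for j in range(i + 1, n):
            cls = bin_ca_distance(float(np.linalg.norm(cas[i] - cas[j])))
            if cls is not None:
                edges.append((i, j, cls))
    return PocketGraph(residues=admitted, vertex_onehots=onehots, edges=edges)


def extract_pocket(
    pdb_text: str,
    ligand_code: str,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> PocketGraph:
    """Full pipeline: PDB text → contact residues → pocket graph."""
    protein, ligand = parse_pdb_complex(pdb_text, ligand_code)
    contacts = extract_contact_residues(protein, ligand, contact_cutoff)
    return build_pocket_graph(contacts)


# -- plain-text pocket format (lossless for graph purposes) -----------------

def write_pocket(graph: PocketGraph) -> str:
    """Serialize a pocket graph to the versioned text format."""
    lines = [f"#pocketgraph v1 n={graph.n_vertices} m={len(graph.edges)}"]
    for res in graph.residues:
        x, y, z = res.ca_coord
        lines.append(
            f"r\t{res.chain_id}\t{res.seq_number}{res.insertion_code.strip()}"
            f"\t{res.aa3}\t{x:.3f}\t{y:.3f}\t{z:.3f}"
        )
    for i, j, cls in graph.edges:
        lines.append(f"{i}\t{j}\t{cls}")
    return "\n".join(lines) + "\n"


def read_pocket(text: str) -> PocketGraph:
    """Reload a pocket graph written by :func:`write_pocket`."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#pocketgraph v1"):
        raise ValueError("not a pocketgraph v1 file")
    residues: list[Residue] = []
    edges: list[tuple[int, int, str]] = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if parts[0] == "r":
            _, chain, seq, aa3, x, y, z = parts
            num = int("".join(c for c in seq if c.isdigit() or c == "-"))
            icode = "".join(c for c in seq if c.isalpha()) or " "
            ca = np.array([float(x), float(y), float(z)])
            residues.append(
                Residue(chain_id=chain, seq_number=num, aa3=aa3,
                        ca_coord=ca, heavy_atom_coords=[ca],
                        insertion_code=icode)
            )
        else:
            i, j, cls = parts
            edges.append((int(i), int(j), cls))
    onehots = np.stack([residue_one_hot(r.aa3) for r in residues])
    return PocketGraph(residues=residues, vertex_onehots=onehots, edges=edges)
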