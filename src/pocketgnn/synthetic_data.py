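"""Synthetic fixtures: toy complexes and planted-rule activity datasets.

Real screening corpora (active/decoy libraries plus co-crystallized
pocket structures) require external downloads, so the package carries a
generator for each input the pipeline consumes:

* toy PDB complexes with residues planted at known minimum distances
  from the ligand, giving an exact ground-truth contact set for any
  cutoff;
* pocket populations: residues placed by a random compact 3D point
  process, typed, and converted through the real distance-binning code
  (so the full geometric path is exercised, never sampled edge classes);
* labeled (compound, pocket) pairs under a planted conjunctive rule:
  a pair is active iff the compound contains a required substructure
  (default: an ether oxygen, i.e. an O bonded to two carbons) AND the
  pocket contains at least k residues of a required type (default: 3
  tryptophans), optionally corrupted by label noise.

The conjunction is the point: neither motif alone determines the label,
so a model can only separate the classes by using both branches — a
desk-scale stand-in for the claim that pocket structure carries
predictive signal.  Compounds are small drug-like heavy-atom graphs
(5–9 atoms: alkane / ether / alcohol / amine scaffolds); pockets have
10–16 residues in a ~12 Å box, the scale of a ligand-contact shell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_graph import MolecularGraph, parse_smiles
from .pocket_graph import (
    PocketGraph, Residue, STANDARD_AA3, build_pocket_graph,
)
from .training import LabeledPair

#: combo sampling order: (both motifs, compound only, pocket only, neither)
BALANCED_COMBO_PROBS = (0.5, 1 / 6, 1 / 6, 1 / 6)
#: pocket-dominated mixture for pocket-ablation experiments: every compound
#: carries the motif, so the pocket alone decides the label
POCKET_DEPENDENT_COMBO_PROBS = (0.5, 0.5, 0.0, 0.0)

_NON_MOTIF_AA = tuple(aa for aa in STANDARD_AA3 if aa != "TRP")


@dataclass(frozen=True)
class PlantedRule:
    """Conjunctive activity rule: compound motif AND pocket motif.

    With ``noise_rate`` 0 the rule is deterministic and its
    Bayes-optimal AUROC is 1.0; otherwise each label flips
    independently with probability ``noise_rate``.
    """

    pocket_motif_aa3: str = "TRP"
    pocket_motif_min_count: int = 3
    compound_motif: str = "ether-oxygen"
    noise_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.noise_rate < 0.5):
            raise ValueError("noise_rate must be in [0, 0.5)")

    def compound_satisfied(self, graph: MolecularGraph) -> bool:
        if self.compound_motif != "ether-oxygen":
            raise ValueError(f"unknown compound motif {self.compound_motif!r}")
        return compound_has_ether_oxygen(graph)

    def pocket_satisfied(self, pocket: PocketGraph) -> bool:
        count = sum(lab == self.pocket_motif_aa3 for lab in pocket.vertex_labels)
        return count >= self.pocket_motif_min_count

    def pre_noise_label(self, compound: MolecularGraph, pocket: PocketGraph) -> int:
        return int(self.compound_satisfied(compound)
                   and self.pocket_satisfied(pocket))


def compound_has_ether_oxygen(graph: MolecularGraph) -> bool:
    """True if some non-aromatic oxygen is bonded to two or more carbons."""
    neighbors: list[list[str]] = [[] for _ in graph.vertex_labels]
    for i, j, _ in graph.edges:
        neighbors[i].append(graph.vertex_labels[j])
        neighbors[j].append(graph.vertex_labels[i])
    for lab, neigh in zip(graph.vertex_labels, neighbors):
        if lab == "O" and sum(n == "C" for n in neigh) >= 2:
            return True
    return False


# -- toy complexes with exact contact geometry ------------------------------

@dataclass
class ToyComplex:
    """A synthetic PDB complex with known residue–ligand distances."""

    pdb_text: str
    planned_distances: list[float]
    ligand_code: str = "LIG"

    def contact_set(self, cutoff: float) -> set[int]:
        """Ground-truth contact residue indices for any cutoff."""
        return {i for i, d in enumerate(self.planned_distances) if d <= cutoff}


def _pdb_atom_line(record: str, serial: int, name: str, resname: str,
                   chain: str, resseq: int, coord: np.ndarray,
                   element: str) -> str:
    x, y, z = coord
    return (
        f"{record:<6s}{serial:5d} {name:<4s}{'':1s}{resname:>3s} {chain}"
        f"{resseq:4d}{'':1s}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def generate_toy_complex_pdb(
    n_residues: int,
    n_ligand_atoms: int,
    contact_plan: list[float],
    seed: int,
) -> ToyComplex:
    """Emit a valid PDB complex with planted residue–ligand distances.

    Ligand heavy atoms sit on the −x axis with the first at the origin;
    residue i puts its nearest atom (CB) exactly ``contact_plan[i]`` Å
    from the origin in a +x half-space direction, with its CA 1.5 Å
    further out, so the minimum heavy-atom distance to the ligand is
    the planned one by construction.  Identical seeds give identical
    file bytes.
    """
    if len(contact_plan) != n_residues:
        raise ValueError("contact_plan length must equal n_residues")
    if n_ligand_atoms < 1 or n_residues < 1:
        raise ValueError("need at least one residue and one ligand atom")
    if any(d <= 0 for d in contact_plan):
        raise ValueError("planned distances must be positive")

    rng = np.random.default_rng(seed)
    lines = []
    serial = 1
    aa_cycle = ("ALA", "LEU", "SER", "THR", "VAL", "PHE")
    for i, dist in enumerate(contact_plan):
        # random unit direction with a safely positive x component
        while True:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            if u[0] >= 0.3:
                break
        resname = aa_cycle[i % len(aa_cycle)]
        ca = (dist + 1.5) * u
        cb = dist * u
        lines.append(_pdb_atom_line("ATOM", serial, "CA", resname, "A",
                                    i + 1, ca, "C"))
        serial += 1
        lines.append(_pdb_atom_line("ATOM", serial, "CB", resname, "A",
                                    i + 1, cb, "C"))
        serial += 1
    for k in range(n_ligand_atoms):
        coord = np.array([-1.5 * k, 0.0, 0.0])
        lines.append(_pdb_atom_line("HETATM", serial, f"C{k + 1}", "LIG", "A",
                                    900, coord, "C"))
        serial += 1
    lines.append("END")
    return ToyComplex(pdb_text="\n".join(lines) + "\n",
                      planned_distances=list(contact_plan))


# -- pocket populations -----------------------------------------------------

def _compact_points(n: int, rng: np.random.Generator,
                    box: float = 12.0, min_sep: float = 3.6) -> np.ndarray:
    """Sequential rejection sampling of n points with a minimum spacing."""
    points: list[np.ndarray] = []
    attempts = 0
    while len(points) < n:
        p = rng.uniform(0, box, size=3)
        if all(np.linalg.norm(p - q) >= min_sep for q in points):
            points.append(p)
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not place pocket residues; box too dense")
    return np.array(points)


def generate_pocket_graph(
    size: int, with_motif: bool, rule: PlantedRule, rng: np.random.Generator
) -> PocketGraph:
    """One pocket: compact random Cα coordinates, typed residues.

    Motif pockets receive k (or k+1 for large pockets) residues of the
    motif type; non-motif pockets receive at most one — below threshold
    but occasionally present, so the count criterion matters.  Edges
    come from the real Cα-distance binning, never sampled directly.
    """
    coords = _compact_points(size, rng)
    if with_motif:
        n_motif = rule.pocket_motif_min_count + (1 if size >= 13 else 0)
    else:
        n_motif = int(rng.random() < 0.3)  # sub-threshold stray motif residue
    types = [str(rng.choice(_NON_MOTIF_AA)) for _ in range(size)]
    motif_positions = rng.choice(size, size=n_motif, replace=False)
    for p in motif_positions:
        types[p] = rule.pocket_motif_aa3
    residues = [
        Residue(chain_id="A", seq_number=i + 1, aa3=types[i],
                ca_coord=coords[i], heavy_atom_coords=[coords[i]])
        for i in range(size)
    ]
    return build_pocket_graph(residues)


def generate_pocket_population(
    n_pockets: int,
    size_range: tuple[int, int],
    rule: PlantedRule,
    seed: int,
) -> list[tuple[PocketGraph, bool]]:
    """Pockets with alternating motif status (~half satisfy the motif)."""
    lo, hi = size_range
    if not (3 <= lo <= hi <= 50):
        raise ValueError("size_range must lie within [3, 50]")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_pockets):
        size = int(rng.integers(lo, hi + 1))
        with_motif = i % 2 == 0
        pocket = generate_pocket_graph(size, with_motif, rule, rng)
        out.append((pocket, rule.pocket_satisfied(pocket)))
    return out


# -- compound generation ----------------------------------------------------

def _branch(tokens: list[str], rng: np.random.Generator) -> list[str]:
    """Maybe attach one methyl branch to a random carbon token."""
    if rng.random() < 0.4:
        c_positions = [k for k, t in enumerate(tokens) if t == "C"]
        k = int(rng.choice(c_positions))
        tokens = tokens[:k + 1] + ["(C)"] + tokens[k + 1:]
    return tokens


def generate_compound_smiles(with_motif: bool, rng: np.random.Generator) -> str:
    """A small drug-like SMILES; motif compounds are chain ethers.

    Non-motif scaffolds (alkanes, primary alcohols, primary amines)
    contain no oxygen with two carbon neighbors — an alcohol's terminal
    hydroxyl oxygen has one, which only a radius ≥ 1 fingerprint can
    tell apart from an ether oxygen.
    """
    n = int(rng.integers(5, 9))  # heavy atoms before branching
    if with_motif:
        a = int(rng.integers(1, n - 1))
        tokens = ["C"] * a + ["O"] + ["C"] * (n - 1 - a)
    else:
        kind = rng.choice(["alkane", "alcohol", "amine"])
        if kind == "alkane":
            tokens = ["C"] * n
        elif kind == "alcohol":
            tokens = ["C"] * (n - 1) + ["O"]
        else:
            tokens = ["C"] * (n - 1) + ["N"]
    return "".join(_branch(tokens, rng))


# -- labeled pair datasets --------------------------------------------------

def generate_labeled_pairs(
    n_pairs: int,
    rule: PlantedRule,
    seed: int,
    combo_probs: tuple[float, float, float, float] = BALANCED_COMBO_PROBS,
    size_range: tuple[int, int] = (10, 16),
    panel_size: int = 40,
) -> list[LabeledPair]:
    """Planted-rule dataset of (compound, pocket, label) pairs.

    Pockets come from a fixed target panel (``panel_size`` pockets,
    half carrying the motif), mirroring the structure of screening
    corpora where many compounds are assayed against the same targets;
    each pair draws a fresh compound and a panel pocket of the wanted
    motif status.  ``combo_probs`` gives the sampling probabilities of
    (both motifs, compound only, pocket only, neither); the balanced
    default puts the label prevalence at 50% and leaves each single
    motif uninformative enough that only the conjunction separates the
    classes.  Each pair's ``meta`` records the SMILES, pocket panel
    index, motif flags and pre-noise label for oracle checks.
    """
    if n_pairs < 20:
        raise ValueError("need at least 20 pairs for a meaningful dataset")
    if panel_size < 2 or panel_size % 2:
        raise ValueError("panel_size must be even and at least 2")
    probs = np.asarray(combo_probs, dtype=float)
    if probs.shape != (4,) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("combo_probs must be 4 probabilities summing to 1")
    rng = np.random.default_rng(seed)

    panel: list[PocketGraph] = []
    panel_motif: list[bool] = []
    for i in range(panel_size):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        with_motif = i % 2 == 0
        panel.append(generate_pocket_graph(size, with_motif, rule, rng))
        panel_motif.append(with_motif)
    motif_ids = [i for i, m in enumerate(panel_motif) if m]
    plain_ids = [i for i, m in enumerate(panel_motif) if not m]

    pairs: list[LabeledPair] = []
    for _ in range(n_pairs):
        combo = int(rng.choice(4, p=probs))
        want_c = combo in (0, 1)
        want_p = combo in (0, 2)
        smiles = generate_compound_smiles(want_c, rng)
        compound = parse_smiles(smiles)
        assert isinstance(compound, MolecularGraph)
        pocket_id = int(rng.choice(motif_ids if want_p else plain_ids))
        pocket = panel[pocket_id]
        pre = rule.pre_noise_label(compound, pocket)
        label = pre ^ int(rng.random() < rule.noise_rate)
        pairs.append(LabeledPair(
            compound=compound, pocket=pocket, label=label,
            meta={
                "smiles": smiles,
                "pocket_id": pocket_id,
                "compound_motif": rule.compound_satisfied(compound),
                "pocket_motif": rule.pocket_satisfied(pocket),
                "pre_noise_label": pre,
            },
        ))
    return pairs
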