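"""r-radius subgraph fingerprints and embedding vocabularies.

The embedding unit of both network branches is the r-radius subgraph:
the neighborhood of a vertex (or edge) within r hops, identified up to
isomorphism.  Canonical identifiers are computed by iterative sorted
neighborhood relabeling (Weisfeiler–Lehman colouring): at step 0 a
vertex's fingerprint is its own label; at step t it is its step t−1
fingerprint combined with the sorted multiset of (incident edge label,
neighbor step t−1 fingerprint) pairs.  An edge fingerprint combines the
edge's own label with the unordered pair of its endpoints' step-r
fingerprints.  Isomorphic neighborhoods always receive identical
fingerprints, and refining from r to r+1 never merges two distinct
classes — the contract the tests pin down.

Fingerprints are deterministic strings (no process-salted hashing), so
vocabularies are reproducible across runs and platforms.

Works on any labeled graph exposing ``vertex_labels`` (list of str) and
``edges`` (list of ``(i, j, label)`` with i < j), i.e. both
:class:`~pocketgnn.chem_graph.MolecularGraph` and
:class:`~pocketgnn.pocket_graph.PocketGraph`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

UNK = "<UNK>"


def _adjacency(graph) -> list[list[tuple[int, str]]]:
    adj: list[list[tuple[int, str]]] = [[] for _ in graph.vertex_labels]
    for i, j, lab in graph.edges:
        adj[i].append((j, lab))
        adj[j].append((i, lab))
    return adj


def all_vertex_fingerprints(graph, r: int) -> list[str]:
    """Step-r fingerprints of every vertex, by iterative relabeling."""
    if r < 0:
        raise ValueError("radius must be non-negative")
    fps = [str(lab) for lab in graph.vertex_labels]
    adj = _adjacency(graph)
    for _ in range(r):
        nxt = []
        for v, fp in enumerate(fps):
            neigh = sorted(f"{elab},{fps[u]}" for u, elab in adj[v])
            nxt.append(f"({fp}|{';'.join(neigh)})")
        fps = nxt
    return fps


def vertex_fingerprint(graph, v: int, r: int) -> str:
    """Canonical identifier of the r-hop neighborhood of vertex ``v``."""
    return all_vertex_fingerprints(graph, r)[v]


def edge_fingerprint(graph, edge: tuple[int, int], r: int) -> str:
    """Canonical identifier of an edge with its endpoints' r-neighborhoods.

    Symmetric in the endpoint order by construction (sorted pair).
    """
    i, j = edge
    labels = {(min(a, b), max(a, b)): lab for a, b, lab in graph.edges}
    key = (min(i, j), max(i, j))
    if key not in labels:
        raise ValueError(f"({i}, {j}) is not an edge of the graph")
    fps = all_vertex_fingerprints(graph, r)
    a, b = sorted((fps[i], fps[j]))
    return f"[{labels[key]}|{a}~{b}]"


def all_edge_fingerprints(graph, r: int) -> list[str]:
    """Fingerprints of every edge, aligned with ``graph.edges`` order."""
    fps = all_vertex_fingerprints(graph, r)
    out = []
    for i, j, lab in graph.edges:
        a, b = sorted((fps[i], fps[j]))
        out.append(f"[{lab}|{a}~{b}]")
    return out


@dataclass
class SubgraphVocabulary:
    """Frozen mapping from canonical fingerprints to embedding indices.

    Index 0 in each map is the reserved UNK entry absorbing any
    fingerprint not seen at fit time (test compounds and pockets will
    contain novel neighborhoods).
    """

    radius: int
    vertex_map: dict[str, int]
    edge_map: dict[str, int]

    @property
    def n_vertex(self) -> int:
        return len(self.vertex_map)

    @property
    def n_edge(self) -> int:
        return len(self.edge_map)

    def to_text(self) -> str:
        lines = [f"#subgraphvocab v1 r={self.radius}"]
        for fp, idx in sorted(self.vertex_map.items(), key=lambda kv: kv[1]):
            lines.append(f"V\t{idx}\t{fp}")
        for fp, idx in sorted(self.edge_map.items(), key=lambda kv: kv[1]):
            lines.append(f"E\t{idx}\t{fp}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SubgraphVocabulary":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines or not lines[0].startswith("#subgraphvocab v1"):
            raise ValueError("not a subgraphvocab v1 file")
        radius = int(lines[0].split("r=")[1])
        vmap: dict[str, int] = {}
        emap: dict[str, int] = {}
        for ln in lines[1:]:
            kind, idx, fp = ln.split("\t", 2)
            (vmap if kind == "V" else emap)[fp] = int(idx)
        return cls(radius=radius, vertex_map=vmap, edge_map=emap)


def build_vocabulary(graphs: Iterable, r: int) -> SubgraphVocabulary:
    """Fit fingerprint→index maps over a training collection.

    First-seen order assigns indices (after UNK at 0), so fitting is
    deterministic given the input order and idempotent under repeats.
    """
    vmap: dict[str, int] = {UNK: 0}
    emap: dict[str, int] = {UNK: 0}
    n_graphs = 0
    for g in graphs:
        n_graphs += 1
        for fp in all_vertex_fingerprints(g, r):
            if fp not in vmap:
                vmap[fp] = len(vmap)
        for fp in all_edge_fingerprints(g, r):
            if fp not in emap:
                emap[fp] = len(emap)
    if n_graphs == 0:
        raise ValueError("cannot fit a vocabulary on an empty collection")
    return SubgraphVocabulary(radius=r, vertex_map=vmap, edge_map=emap)


@dataclass
class IndexedGraph:
    """A graph mapped through a vocabulary, ready for embedding lookup."""

    vertex_indices: list[int]
    edge_list: list[tuple[int, int, int]]  # (i, j, edge vocab index)
    adjacency: list[list[tuple[int, int]]]  # per vertex: (neighbor, edge pos)
    n_unknown: int = 0

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_indices)


def index_graph(graph, vocab: SubgraphVocabulary) -> IndexedGraph:
    """Map a graph's fingerprints through a fitted vocabulary.

    Unseen fingerprints index to UNK; the count is recorded on the
    result so callers can log novelty rates.
    """
    vfps = all_vertex_fingerprints(graph, vocab.radius)
    efps = all_edge_fingerprints(graph, vocab.radius)
    unk = 0
    vidx = []
    for fp in vfps:
        k = vocab.vertex_map.get(fp, 0)
        unk += fp not in vocab.vertex_map
        vidx.append(k)
    edge_list = []
    adjacency: list[list[tuple[int, int]]] = [[] for _ in vidx]
    for pos, ((i, j, _), fp) in enumerate(zip(graph.edges, efps)):
        k = vocab.edge_map.get(fp, 0)
        unk += fp not in vocab.edge_map
        edge_list.append((i, j, k))
        adjacency[i].append((j, pos))
        adjacency[j].append((i, pos))
    return IndexedGraph(
        vertex_indices=vidx, edge_list=edge_list, adjacency=adjacency,
        n_unknown=unk,
    )
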