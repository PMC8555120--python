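"""Independent brute-force oracles and graph helpers shared by the tests.

Everything here is deliberately naive — literal interval checks, O(n^2)
pairwise counts, explicit neighborhood extraction + VF2 isomorphism —
so the implementation under test is never on both sides of a comparison.
"""

from __future__ import annotations

from fractions import Fraction

import networkx as nx
import numpy as np

from pocketgnn.chem_graph import MolecularGraph


def auroc_pairwise(scores, labels) -> float:
    """Mann–Whitney statistic by explicit pair counting with tie credit."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    num = Fraction(0)
    for sp in pos:
        for sn in neg:
            if sp > sn:
                num += 1
            elif sp == sn:
                num += Fraction(1, 2)
    return float(num / (len(pos) * len(neg)))


def bin_distance_literal(d: float) -> str | None:
    """The five printed intervals, written out one by one, half-open."""
    if 1.0 <= d < 4.8:
        return "I"
    if 4.8 <= d < 7.0:
        return "II"
    if 7.0 <= d < 9.2:
        return "III"
    if 9.2 <= d < 11.4:
        return "IV"
    if 11.4 <= d < 13.6:
        return "V"
    return None


def pocket_edges_bruteforce(ca_coords: np.ndarray) -> set[tuple[int, int, str]]:
    """Double loop over all residue pairs with literal interval checks."""
    n = len(ca_coords)
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(ca_coords[i] - ca_coords[j]))
            cls = bin_distance_literal(d)
            if cls is not None:
                out.add((i, j, cls))
    return out


def random_labeled_graph(rng: np.random.Generator, max_vertices: int = 8,
                         n_vertex_labels: int = 3, n_edge_labels: int = 2
                         ) -> MolecularGraph:
    """Random connected-ish labeled graph for fingerprint property tests."""
    n = int(rng.integers(1, max_vertices + 1))
    vlabels = [f"L{rng.integers(n_vertex_labels)}" for _ in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.4:
                edges.append((i, j, f"e{rng.integers(n_edge_labels)}"))
    return MolecularGraph(vertex_labels=vlabels, edges=edges)


def permute_graph(graph: MolecularGraph, perm: list[int]) -> MolecularGraph:
    """Relabel vertices: new index of old vertex v is perm[v]."""
    n = graph.n_vertices
    new_labels = [""] * n
    for v, lab in enumerate(graph.vertex_labels):
        new_labels[perm[v]] = lab
    new_edges = []
    for i, j, lab in graph.edges:
        a, b = perm[i], perm[j]
        if a > b:
            a, b = b, a
        new_edges.append((a, b, lab))
    return MolecularGraph(vertex_labels=new_labels, edges=sorted(new_edges))


def to_networkx(graph) -> nx.Graph:
    g = nx.Graph()
    for v, lab in enumerate(graph.vertex_labels):
        g.add_node(v, label=lab)
    for i, j, lab in graph.edges:
        g.add_edge(i, j, label=lab)
    return g


def rooted_balls_isomorphic(graph, u: int, v: int, r: int) -> bool:
    """Isomorphism of the r-hop neighborhoods rooted at u and v (VF2)."""
    g = to_networkx(graph)
    balls = []
    for root in (u, v):
        ball = nx.ego_graph(g, root, radius=r)
        ball = ball.copy()
        for node in ball.nodes:
            ball.nodes[node]["is_root"] = node == root
        balls.append(ball)
    return nx.is_isomorphic(
        balls[0], balls[1],
        node_match=lambda a, b: a["label"] == b["label"]
        and a["is_root"] == b["is_root"],
        edge_match=lambda a, b: a["label"] == b["label"],
    )


def molgraphs_isomorphic(g1, g2) -> bool:
    return nx.is_isomorphic(
        to_networkx(g1), to_networkx(g2),
        node_match=lambda a, b: a["label"] == b["label"],
        edge_match=lambda a, b: a["label"] == b["label"],
    )
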