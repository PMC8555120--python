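"""Graph neural network forward pass, classifier head, and gradients.

Each branch (compound and pocket) turns an indexed graph into one
d-dimensional vector in three parts:

* embedding — row lookup of every r-radius vertex and edge fingerprint
  in the branch's embedding tables;
* transition — L rounds of neighborhood aggregation with per-layer
  weights W_l and a ReLU nonlinearity,

      h_i' = relu( h_i + sum_{j in N(i)} W_l (h_j + e_ij) ),

  a residual "add the adjacent vertex and edge vectors, then update
  through the nonlinearity" step; edge vectors stay fixed across layers;
* averaging — the arithmetic mean of the final vertex vectors.

The classifier concatenates the two branch outputs in fixed order
[y_molecule; y_protein] and applies a linear map to two logits,

    z = W_output [y_molecule; y_protein] + b_output,   z = [y_0, y_1],

followed by a softmax; index 1 is the active class.  Everything is
plain NumPy (float64); gradients of the cross-entropy loss with respect
to every parameter are computed analytically by backpropagation and are
validated against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .subgraph_vocab import IndexedGraph


@dataclass
class BranchParameters:
    """Embedding tables and per-layer transition weights of one branch."""

    vertex_embeddings: np.ndarray  # (|vertex vocab|, d)
    edge_embeddings: np.ndarray    # (|edge vocab|, d)
    transition_weights: list[np.ndarray]  # L matrices (d, d)

    @property
    def n_layers(self) -> int:
        return len(self.transition_weights)

    @property
    def dim(self) -> int:
        return self.vertex_embeddings.shape[1]


@dataclass
class GNNParameters:
    """All trainable parameters of the two-branch model.

    The two branches have separate parameter sets: their vocabularies
    and graph semantics differ.  ``W_output`` is (2, 2d) and acts on the
    ordered concatenation [y_molecule; y_protein]; row/logit index 1 is
    the active class.
    """

    compound: BranchParameters
    pocket: BranchParameters
    W_output: np.ndarray  # (2, 2d)
    b_output: np.ndarray  # (2,)

    @property
    def dim(self) -> int:
        return self.compound.dim

    def named_arrays(self):
        """Flat (name, array) view used by the optimizer and checks."""
        for branch_name in ("compound", "pocket"):
            br: BranchParameters = getattr(self, branch_name)
            yield f"{branch_name}.vertex_embeddings", br.vertex_embeddings
            yield f"{branch_name}.edge_embeddings", br.edge_embeddings
            for l, W in enumerate(br.transition_weights):
                yield f"{branch_name}.W{l}", W
        yield "W_output", self.W_output
        yield "b_output", self.b_output


def init_parameters(
    n_vertex_compound: int, n_edge_compound: int,
    n_vertex_pocket: int, n_edge_pocket: int,
    d: int, layers_compound: int, layers_pocket: int,
    rng: np.random.Generator,
) -> GNNParameters:
    """Scaled-uniform initialization; fully determined by ``rng``."""
    def branch(nv: int, ne: int, L: int) -> BranchParameters:
        a = 1.0 / np.sqrt(d)
        return BranchParameters(
            vertex_embeddings=rng.uniform(-0.1, 0.1, size=(nv, d)),
            edge_embeddings=rng.uniform(-0.1, 0.1, size=(ne, d)),
            transition_weights=[rng.uniform(-a, a, size=(d, d)) for _ in range(L)],
        )

    comp = branch(n_vertex_compound, n_edge_compound, layers_compound)
    pock = branch(n_vertex_pocket, n_edge_pocket, layers_pocket)
    a_out = 1.0 / np.sqrt(2 * d)
    return GNNParameters(
        compound=comp, pocket=pock,
        W_output=rng.uniform(-a_out, a_out, size=(2, 2 * d)),
        b_output=np.zeros(2),
    )


# -- graph array cache ------------------------------------------------------

def _graph_arrays(ig: IndexedGraph):
    """Directed-incidence arrays (src, dst, edge position) for a graph.

    Cached on the IndexedGraph instance; each undirected edge appears
    once per direction so the neighbor sum is a single scatter-add.
    """
    cached = getattr(ig, "_arrays", None)
    if cached is not None:
        return cached
    vidx = np.asarray(ig.vertex_indices, dtype=np.intp)
    if ig.edge_list:
        i = np.array([e[0] for e in ig.edge_list], dtype=np.intp)
        j = np.array([e[1] for e in ig.edge_list], dtype=np.intp)
        k = np.array([e[2] for e in ig.edge_list], dtype=np.intp)
        src = np.concatenate([i, j])
        dst = np.concatenate([j, i])
        pos = np.concatenate([np.arange(len(i)), np.arange(len(i))])
    else:
        src = dst = pos = np.empty(0, dtype=np.intp)
        k = np.empty(0, dtype=np.intp)
    arrays = (vidx, k, src, dst, pos)
    ig._arrays = arrays
    return arrays


# -- forward operations -----------------------------------------------------

def embed(ig: IndexedGraph, branch: BranchParameters) -> tuple[np.ndarray, np.ndarray]:
    """Row lookups: (n, d) vertex vectors and (m, d) edge vectors."""
    vidx, eidx, *_ = _graph_arrays(ig)
    if vidx.size and vidx.max() >= branch.vertex_embeddings.shape[0]:
        raise IndexError("vertex index out of embedding-table bounds")
    if eidx.size and eidx.max() >= branch.edge_embeddings.shape[0]:
        raise IndexError("edge index out of embedding-table bounds")
    return branch.vertex_embeddings[vidx], branch.edge_embeddings[eidx]


def transition_step(
    vertex_vecs: np.ndarray,
    edge_vecs: np.ndarray,
    adjacency: list[list[tuple[int, int]]],
    W: np.ndarray,
) -> np.ndarray:
    """One aggregation round h_i' = relu(h_i + Σ_j W (h_j + e_ij)).

    Isolated vertices reduce to relu(h_i).  Edge vectors are read, not
    written.
    """
    n, d = vertex_vecs.shape
    if W.shape != (d, d):
        raise ValueError(f"weight shape {W.shape} incompatible with d={d}")
    s = vertex_vecs.copy()
    for i, neigh in enumerate(adjacency):
        for j, pos in neigh:
            s[i] += W @ (vertex_vecs[j] + edge_vecs[pos])
    return np.maximum(s, 0.0)


def _forward_branch(ig: IndexedGraph, branch: BranchParameters, n_layers=None):
    """Vectorized forward pass; returns (y, cache) for backprop."""
    H, EE = embed(ig, branch)
    _, _, src, dst, pos = _graph_arrays(ig)
    weights = branch.transition_weights
    if n_layers is not None:
        weights = weights[:n_layers]
    Hs = [H]
    masks = []
    for W in weights:
        S = Hs[-1].copy()
        if src.size:
            msg = (Hs[-1][src] + EE[pos]) @ W.T
            np.add.at(S, dst, msg)
        mask = S > 0
        masks.append(mask)
        Hs.append(np.where(mask, S, 0.0))
    y = Hs[-1].mean(axis=0)
    return y, (Hs, masks, EE, weights)


def readout_average(vertex_vecs: np.ndarray) -> np.ndarray:
    """Mean over vertices; the branch output y."""
    if vertex_vecs.shape[0] == 0:
        raise ValueError("cannot average an empty vertex set")
    return vertex_vecs.mean(axis=0)


def encode_graph(
    ig: IndexedGraph, branch: BranchParameters, n_layers: int | None = None
) -> np.ndarray:
    """embed → L transition steps → averaging readout."""
    if n_layers is not None and n_layers < 0:
        raise ValueError("layer count must be non-negative")
    y, _ = _forward_branch(ig, branch, n_layers)
    return y


def softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def classify(
    y_molecule: np.ndarray, y_protein: np.ndarray, params: GNNParameters
) -> tuple[np.ndarray, float]:
    """Logits and active-class probability for one (compound, pocket) pair."""
    d = params.dim
    if y_molecule.shape != (d,) or y_protein.shape != (d,):
        raise ValueError("branch vector dimension mismatch")
    concat = np.concatenate([y_molecule, y_protein])
    z = params.W_output @ concat + params.b_output
    p = softmax(z)
    return z, float(p[1])


def forward_pair(
    ig_compound: IndexedGraph, ig_pocket: IndexedGraph, params: GNNParameters
) -> float:
    """Active-class probability for one pair (inference path)."""
    y_mol = encode_graph(ig_compound, params.compound)
    y_prot = encode_graph(ig_pocket, params.pocket)
    _, p_active = classify(y_mol, y_prot, params)
    return p_active


# -- backward pass ----------------------------------------------------------

def zero_gradients(params: GNNParameters) -> dict[str, np.ndarray]:
    return {name: np.zeros_like(arr) for name, arr in params.named_arrays()}


def _backward_branch(ig, branch, cache, dY, grads, prefix):
    Hs, masks, EE, weights = cache
    _, eidx, src, dst, pos = _graph_arrays(ig)
    n = Hs[0].shape[0]
    dH = np.broadcast_to(dY / n, Hs[-1].shape).copy()
    dEE = np.zeros_like(EE)
    for l in range(len(weights) - 1, -1, -1):
        W = weights[l]
        dS = dH * masks[l]
        dH = dS.copy()
        if src.size:
            X = Hs[l][src] + EE[pos]
            grads[f"{prefix}.W{l}"] += dS[dst].T @ X
            dX = dS[dst] @ W
            np.add.at(dH, src, dX)
            np.add.at(dEE, pos, dX)
    vidx = np.asarray(ig.vertex_indices, dtype=np.intp)
    np.add.at(grads[f"{prefix}.vertex_embeddings"], vidx, dH)
    if eidx.size:
        np.add.at(grads[f"{prefix}.edge_embeddings"], eidx, dEE)


def loss_and_gradients(
    ig_compound: IndexedGraph,
    ig_pocket: IndexedGraph,
    label: int,
    params: GNNParameters,
    grads: dict[str, np.ndarray] | None = None,
) -> tuple[float, dict[str, np.ndarray], float]:
    """Cross-entropy loss, parameter gradients, and p_active for one pair.

    Gradients accumulate into ``grads`` if given (mini-batching), else a
    fresh zeroed dict is used.
    """
    if grads is None:
        grads = zero_gradients(params)
    d = params.dim
    y_mol, cache_c = _forward_branch(ig_compound, params.compound)
    y_prot, cache_p = _forward_branch(ig_pocket, params.pocket)
    concat = np.concatenate([y_mol, y_prot])
    z = params.W_output @ concat + params.b_output
    p = softmax(z)
    loss = -np.log(max(p[label], 1e-300))

    dz = p.copy()
    dz[label] -= 1.0
    grads["W_output"] += np.outer(dz, concat)
    grads["b_output"] += dz
    dconcat = params.W_output.T @ dz
    _backward_branch(ig_compound, params.compound, cache_c, dconcat[:d],
                     grads, "compound")
    _backward_branch(ig_pocket, params.pocket, cache_p, dconcat[d:],
                     grads, "pocket")
    return float(loss), grads, float(p[1])
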