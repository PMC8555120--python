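"""End-to-end training of the two-branch model and the classifier head.

Defaults reproduce the reference hyperparameter set: feature
dimension 10, compound subgraph radius 2, pocket subgraph radius 1,
three transition layers per branch, Adam at learning rate 0.001 halved
every 10 epochs, 100 epochs, batch size 1.  The loss is the mean
cross-entropy of the softmax output — the canonical companion of a
softmax classifier.  No early stopping, weight decay, or dropout: none
appear in the hyperparameter table, so none exist here.

Training sets are balanced by 1:1 down-sampling of decoys, matching the
treatment of the active/decoy screening corpora the method was built
for (order 30 actives against 15,000 decoys per target).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .chem_graph import MolecularGraph, ExclusionMark
from .pocket_graph import PocketGraph
from .subgraph_vocab import (
    SubgraphVocabulary, IndexedGraph, build_vocabulary, index_graph,
)
from .gnn_core import (
    GNNParameters, BranchParameters, init_parameters, zero_gradients,
    loss_and_gradients, forward_pair,
)

MODEL_FORMAT = "pocketgnn-model"
MODEL_VERSION = 1


@dataclass
class TrainingConfig:
    """Hyperparameters; the reference defaults of the method."""

    dim_d: int = 10
    r_compound: int = 2
    r_pocket: int = 1
    layers_compound: int = 3
    layers_pocket: int = 3
    learning_rate: float = 0.001
    lr_decay: float = 0.5
    decay_interval_epochs: int = 10
    epochs: int = 100
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.lr_decay <= 1):
            raise ValueError("lr_decay must be in (0, 1]")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")


@dataclass
class LabeledPair:
    """One (compound graph, pocket graph, activity label) example."""

    compound: MolecularGraph
    pocket: PocketGraph
    label: int
    meta: dict | None = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (inactive/decoy) or 1 (active)")


def downsample_1to1(
    actives: Sequence[LabeledPair], decoys: Sequence[LabeledPair], seed: int
) -> list[LabeledPair]:
    """Balance classes: keep all actives, subsample decoys to match.

    A uniform random decoy subset of size |actives| is drawn and the
    combined list is shuffled, both driven by ``seed`` alone.
    """
    if len(decoys) < len(actives):
        raise ValueError(
            f"cannot reach a 1:1 ratio: {len(decoys)} decoys < {len(actives)} actives"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(decoys), size=len(actives), replace=False)
    pool = list(actives) + [decoys[i] for i in sorted(chosen)]
    order = rng.permutation(len(pool))
    return [pool[i] for i in order]


def lr_schedule(epoch: int, config: TrainingConfig) -> float:
    """Step decay: lr × decay^floor(epoch / interval), applied at epoch
    boundaries (epochs 10, 20, ... with the default interval)."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return config.learning_rate * config.lr_decay ** (
        epoch // config.decay_interval_epochs
    )


class AdamOptimizer:
    """Adaptive-moment estimation over a named parameter dict."""

    def __init__(self, params: GNNParameters, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(a) for k, a in params.named_arrays()}
        self.v = {k: np.zeros_like(a) for k, a in params.named_arrays()}

    def step(self, params: GNNParameters, grads: dict[str, np.ndarray], lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for name, arr in params.named_arrays():
            g = grads[name]
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            arr -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


@dataclass
class TrainedModel:
    """Everything needed to score new pairs: vocabularies + parameters.

    Class convention (recorded in the serialized header): logits are
    z = [y_0, y_1] and index 1 is the active class.
    """

    config: TrainingConfig
    vocab_compound: SubgraphVocabulary
    vocab_pocket: SubgraphVocabulary
    params: GNNParameters

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        def branch(b: BranchParameters) -> dict:
            return {
                "vertex_embeddings": b.vertex_embeddings.tolist(),
                "edge_embeddings": b.edge_embeddings.tolist(),
                "transition_weights": [W.tolist() for W in b.transition_weights],
            }

        def vocab(v: SubgraphVocabulary) -> dict:
            return {"radius": v.radius, "vertex_map": v.vertex_map,
                    "edge_map": v.edge_map}

        doc = {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "class_convention": "z=[y0,y1]; index 1 = active",
            "config": asdict(self.config),
            "vocab_compound": vocab(self.vocab_compound),
            "vocab_pocket": vocab(self.vocab_pocket),
            "params": {
                "compound": branch(self.params.compound),
                "pocket": branch(self.params.pocket),
                "W_output": self.params.W_output.tolist(),
                "b_output": self.params.b_output.tolist(),
            },
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        doc = json.loads(text)
        if doc.get("format") != MODEL_FORMAT or doc.get("version") != MODEL_VERSION:
            raise ValueError("not a pocketgnn-model v1 file")
        config = TrainingConfig(**doc["config"])

        def vocab(d: dict) -> SubgraphVocabulary:
            return SubgraphVocabulary(
                radius=d["radius"],
                vertex_map={k: int(v) for k, v in d["vertex_map"].items()},
                edge_map={k: int(v) for k, v in d["edge_map"].items()},
            )

        def branch(d: dict) -> BranchParameters:
            return BranchParameters(
                vertex_embeddings=np.asarray(d["vertex_embeddings"], dtype=float),
                edge_embeddings=np.asarray(d["edge_embeddings"], dtype=float),
                transition_weights=[np.asarray(W, dtype=float)
                                    for W in d["transition_weights"]],
            )

        vc = vocab(doc["vocab_compound"])
        vp = vocab(doc["vocab_pocket"])
        params = GNNParameters(
            compound=branch(doc["params"]["compound"]),
            pocket=branch(doc["params"]["pocket"]),
            W_output=np.asarray(doc["params"]["W_output"], dtype=float),
            b_output=np.asarray(doc["params"]["b_output"], dtype=float),
        )
        model = cls(config=config, vocab_compound=vc, vocab_pocket=vp,
                    params=params)
        model._validate()
        return model

    def _validate(self) -> None:
        d = self.config.dim_d
        p = self.params
        if p.W_output.shape != (2, 2 * d) or p.b_output.shape != (2,):
            raise ValueError("output head shape does not match dimension d")
        for br, vocab, L in (
            (p.compound, self.vocab_compound, self.config.layers_compound),
            (p.pocket, self.vocab_pocket, self.config.layers_pocket),
        ):
            if br.vertex_embeddings.shape != (vocab.n_vertex, d):
                raise ValueError("vertex embedding table shape mismatch")
            if br.edge_embeddings.shape != (vocab.n_edge, d):
                raise ValueError("edge embedding table shape mismatch")
            if len(br.transition_weights) != L:
                raise ValueError("transition layer count mismatch")


def _index_pairs(
    pairs: Sequence[LabeledPair],
    vocab_c: SubgraphVocabulary,
    vocab_p: SubgraphVocabulary,
) -> list[tuple[IndexedGraph, IndexedGraph, int]]:
    # pockets recur across pairs (panel structure), so index each object once
    cache: dict[int, IndexedGraph] = {}

    def cached(graph, vocab):
        key = id(graph)
        if key not in cache:
            cache[key] = index_graph(graph, vocab)
        return cache[key]

    return [
        (cached(p.compound, vocab_c), cached(p.pocket, vocab_p), p.label)
        for p in pairs
    ]


def train(
    pairs: Sequence[LabeledPair],
    config: TrainingConfig | None = None,
    log_fn=None,
) -> tuple[TrainedModel, list[float]]:
    """Fit vocabularies and all parameters jointly on labeled pairs.

    Returns the trained model and the per-epoch mean training loss.
    Example order is reshuffled every epoch from the run seed; identical
    seeds and data give bitwise-identical trajectories.
    """
    if config is None:
        config = TrainingConfig()
    if not pairs:
        raise ValueError("no training pairs")
    labels = {p.label for p in pairs}
    if len(labels) < 2:
        warnings.warn("single-class training set; downstream AUROC is undefined")

    vocab_c = build_vocabulary([p.compound for p in pairs], config.r_compound)
    vocab_p = build_vocabulary([p.pocket for p in pairs], config.r_pocket)
    indexed = _index_pairs(pairs, vocab_c, vocab_p)

    rng = np.random.default_rng(config.seed)
    params = init_parameters(
        vocab_c.n_vertex, vocab_c.n_edge, vocab_p.n_vertex, vocab_p.n_edge,
        config.dim_d, config.layers_compound, config.layers_pocket, rng,
    )
    optimizer = AdamOptimizer(params)

    history: list[float] = []
    n = len(indexed)
    for epoch in range(config.epochs):
        lr = lr_schedule(epoch, config)
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            grads = zero_gradients(params)
            batch_loss = 0.0
            for idx in batch:
                ig_c, ig_p, label = indexed[idx]
                loss, grads, _ = loss_and_gradients(ig_c, ig_p, label, params, grads)
                batch_loss += loss
            for g in grads.values():
                g /= len(batch)
            optimizer.step(params, grads, lr)
            total += batch_loss
        epoch_loss = total / n
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        history.append(epoch_loss)
        if log_fn is not None:
            log_fn(epoch, lr, epoch_loss)

    model = TrainedModel(config=config, vocab_compound=vocab_c,
                         vocab_pocket=vocab_p, params=params)
    return model, history


@dataclass
class PredictionRecord:
    """Score for one input pair, or an explicit exclusion."""

    score: float | None
    excluded: bool = False
    reason: str = ""


def predict(
    pairs: Sequence[tuple[MolecularGraph | ExclusionMark, PocketGraph]],
    model: TrainedModel,
) -> list[PredictionRecord]:
    """Active-class probabilities for (compound, pocket) pairs.

    Compounds carrying an :class:`ExclusionMark` (dot-disconnected
    SMILES) get no score — an explicit per-record exclusion flag instead
    of a silent drop.
    """
    out: list[PredictionRecord] = []
    for compound, pocket in pairs:
        if isinstance(compound, ExclusionMark):
            out.append(PredictionRecord(score=None, excluded=True,
                                        reason=compound.reason))
            continue
        ig_c = index_graph(compound, model.vocab_compound)
        ig_p = index_graph(pocket, model.vocab_pocket)
        out.append(PredictionRecord(score=forward_pair(ig_c, ig_p, model.params)))
    return out
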