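"""Edge classifier fusing a global GIN encoder with a local ego-subgraph
encoder whose members are gated by encoded hop distances.

Architecture (one message-passing layer in each branch):

* input embed: linear map of raw vertex features to `hidden_dim`;
* global branch: GIN update -> FC+ReLU -> dropout -> FC+ReLU -> batchnorm,
  producing n x (hidden_dim // 2) global features;
* local branch: a shared kernel GIN runs over the disjoint union of all
  k-hop egonets; the subgraph part sums each member's embedding weighted by
  a sigmoid gate of its (one-hot encoded) hop distance to the center, the
  centroid part gates the center's own embedding (distance 0); the two are
  summed elementwise and batch-normalized to n x (hidden_dim // 2);
* fusion: concatenation of the two halves;
* head: elementwise product of the two endpoint embeddings -> FC -> sigmoid,
  giving per-category probabilities (endpoint order cannot matter).

The gating unit is one-hot(distance) -> linear -> ReLU -> dropout -> linear
-> sigmoid; hop distances are bounded by 2k inside an egonet, so the one-hot
support is {0, ..., 2k}.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Tensor, concat
from .egonet import EgonetBatch
from .graph import ProteinGraph
from .nn import MLP, BatchNorm1d, Dropout, Linear, Module

__all__ = ["ModelConfig", "EdgeClassifier", "gin_update", "fuse",
           "edge_index_from_graph"]

MODES = ("combined", "global", "local")


@dataclass(frozen=True)
class ModelConfig:
    input_dim: int
    n_categories: int = 7
    hidden_dim: int = 512
    k: int = 1
    dropout_local: float = 0.2
    dropout_global: float = 0.5
    gin_epsilon: float = 0.0
    learnable_epsilon: bool = False
    mode: str = "combined"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.hidden_dim < 2 or self.n_categories < 1:
            raise ValueError("dimensions must be positive (hidden_dim >= 2)")
        if not (0 <= self.dropout_local < 1 and 0 <= self.dropout_global < 1):
            raise ValueError("dropout rates must be in [0, 1)")
        if self.k < 0:
            raise ValueError("hop radius must be >= 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    def to_dict(self) -> dict:
        return asdict(self)


def edge_index_from_graph(graph: ProteinGraph,
                          edge_subset: np.ndarray | None = None) -> np.ndarray:
    """(2, 2E) directed src/dst arrays (each undirected edge doubled)."""
    edges = graph.edges if edge_subset is None else graph.edges[edge_subset]
    if edges.shape[0] == 0:
        return np.zeros((2, 0), dtype=np.intp)
    src = np.concatenate([edges[:, 0], edges[:, 1]])
    dst = np.concatenate([edges[:, 1], edges[:, 0]])
    return np.stack([src, dst])


def gin_update(X: Tensor, edge_index: np.ndarray, mlp: MLP,
               epsilon) -> Tensor:
    """h_v = MLP((1 + eps) * x_v + sum_{u in N(v)} x_u)."""
    n = X.shape[0]
    eps = epsilon if isinstance(epsilon, Tensor) else float(epsilon)
    if edge_index.shape[1] > 0:
        agg = X.take(edge_index[0]).segment_sum(edge_index[1], n)
        h = X * (1.0 + eps) + agg
    else:
        h = X * (1.0 + eps)
    return mlp(h)


def fuse(global_part: Tensor, local_part: Tensor) -> Tensor:
    """Concatenate branch features along the feature axis."""
    if global_part.shape[0] != local_part.shape[0]:
        raise ValueError("branch row counts differ")
    return concat([global_part, local_part], axis=1)


class GatingUnit(Module):
    """one-hot distance -> linear -> ReLU -> dropout -> linear -> sigmoid."""

    def __init__(self, n_distances: int, out_dim: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.lin1 = Linear(n_distances, out_dim, rng)
        self.drop = Dropout(dropout, rng)
        self.lin2 = Linear(out_dim, out_dim, rng)

    def __call__(self, onehot: np.ndarray) -> Tensor:
        h = self.lin1(Tensor(onehot)).relu()
        return self.lin2(self.drop(h)).sigmoid()


class GlobalEncoder(Module):
    def __init__(self, hidden: int, half: int, dropout: float,
                 rng: np.random.Generator, epsilon: float, learnable: bool):
        super().__init__()
        self.gin_mlp = MLP([hidden, hidden, half], rng)
        self.fc1 = Linear(half, half, rng)
        self.drop = Dropout(dropout, rng)
        self.fc2 = Linear(half, half, rng)
        self.bn = BatchNorm1d(half)
        self.epsilon = Tensor(np.array(epsilon), requires_grad=learnable) \
            if learnable else float(epsilon)

    def __call__(self, X: Tensor, edge_index: np.ndarray) -> Tensor:
        h = gin_update(X, edge_index, self.gin_mlp, self.epsilon)
        h = self.drop(self.fc1(h).relu())
        h = self.fc2(h).relu()
        return self.bn(h)


class LocalEncoder(Module):
    """Kernel GIN over the egonet disjoint union with distance gating."""

    def __init__(self, hidden: int, half: int, k: int, dropout: float,
                 rng: np.random.Generator, epsilon: float, learnable: bool):
        super().__init__()
        self.k = k
        self.n_dist = 2 * k + 1
        self.gin_mlp = MLP([hidden, hidden, half], rng)
        self.gate = GatingUnit(self.n_dist, half, dropout, rng)
        self.bn = BatchNorm1d(half)
        self.epsilon = Tensor(np.array(epsilon), requires_grad=learnable) \
            if learnable else float(epsilon)

    def _onehot(self, dist: np.ndarray) -> np.ndarray:
        eye = np.eye(self.n_dist)
        return eye[np.clip(dist, 0, self.n_dist - 1)]

    def branches(self, X: Tensor, batch: EgonetBatch,
                 n_vertices: int) -> tuple[Tensor, Tensor]:
        """(subgraph, centroid) branch features before the sum + batchnorm."""
        Xu = X.take(batch.slot_vertex)
        edge_index = edge_index_from_slots(batch.union_edges)
        h = gin_update(Xu, edge_index, self.gin_mlp, self.epsilon)
        gates = self.gate(self._onehot(batch.slot_dist))
        subgraph = (gates * h).segment_sum(batch.slot_center, n_vertices)
        center_gate = self.gate(self._onehot(np.zeros(1, dtype=np.int64)))
        centroid = h.take(batch.center_slot) * center_gate
        return subgraph, centroid

    def __call__(self, X: Tensor, batch: EgonetBatch, n_vertices: int) -> Tensor:
        subgraph, centroid = self.branches(X, batch, n_vertices)
        return self.bn(subgraph + centroid)


def edge_index_from_slots(union_edges: np.ndarray) -> np.ndarray:
    if union_edges.shape[0] == 0:
        return np.zeros((2, 0), dtype=np.intp)
    src = np.concatenate([union_edges[:, 0], union_edges[:, 1]])
    dst = np.concatenate([union_edges[:, 1], union_edges[:, 0]])
    return np.stack([src, dst])


class EdgeClassifier(Module):
    """Full model: embed -> (global | local | both) -> fuse -> edge head."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.rng = rng
        hidden = config.hidden_dim
        half = hidden // 2
        self.embed = Linear(config.input_dim, hidden, rng)
        self.global_enc = GlobalEncoder(hidden, half, config.dropout_global,
                                        rng, config.gin_epsilon,
                                        config.learnable_epsilon)
        self.local_enc = LocalEncoder(hidden, half, config.k,
                                      config.dropout_local, rng,
                                      config.gin_epsilon,
                                      config.learnable_epsilon)
        head_in = hidden if config.mode == "combined" else half
        self.head = Linear(head_in, config.n_categories, rng)

    # -- forward pieces ---------------------------------------------------

    def vertex_embeddings(self, X: Tensor | np.ndarray, edge_index: np.ndarray,
                          ego: EgonetBatch | None) -> Tensor:
        X = X if isinstance(X, Tensor) else Tensor(X)
        n = X.shape[0]
        Xe = self.embed(X)
        mode = self.config.mode
        if mode == "global":
            return self.global_enc(Xe, edge_index)
        if mode == "local":
            return self.local_enc(Xe, ego, n)
        return fuse(self.global_enc(Xe, edge_index),
                    self.local_enc(Xe, ego, n))

    def predict_edges(self, H: Tensor, edges: np.ndarray) -> Tensor:
        """Per-edge category probabilities; symmetric in endpoint order."""
        edges = np.asarray(edges, dtype=np.intp).reshape(-1, 2)
        n = H.shape[0]
        if edges.size and (edges.min() < 0 or edges.max() >= n):
            raise IndexError("edge endpoint out of range")
        z = self.head(H.take(edges[:, 0]) * H.take(edges[:, 1]))
        # logit clip keeps probabilities strictly inside (0, 1) in float64
        return z.clamp(-30.0, 30.0).sigmoid()

    def forward(self, X, edge_index: np.ndarray, ego: EgonetBatch | None,
                edges: np.ndarray) -> Tensor:
        return self.predict_edges(self.vertex_embeddings(X, edge_index, ego),
                                  edges)

    __call__ = forward
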