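"""Seeded training loop with early stopping on the training loss, plateau
learning-rate decay, best-loss checkpointing, and evaluation.

Message passing is transductive by default: vertex embeddings are computed
on the full graph every step while the loss only sees train edges. The
`inductive` flag restricts message passing (and the egonets) to the
train-edge subgraph for stricter unseen-protein protocols.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .egonet import egonet_batch
from .graph import ProteinGraph
from .losses import ASLParams, asl, bce, focal
from .metrics import MetricsReport, compute_report
from .model import EdgeClassifier, ModelConfig, edge_index_from_graph
from .nn import Adam
from .split import EdgeSplit

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainHistory", "Checkpoint", "train", "evaluate",
           "export_embeddings", "TrainingDiverged"]

THRESHOLD = 0.5


class TrainingDiverged(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 400
    batch_size: int = 1024
    lr: float = 0.01
    patience: int = 20
    lr_decay: float = 0.5
    min_delta: float = 1e-10                # improvement below this is a plateau
    loss: str = "asl"                       # asl | bce | focal
    loss_params: ASLParams = ASLParams()
    focal_gamma: float = 2.0
    seed: int = 0
    inductive: bool = False
    eval_each_epoch: bool = False

    def loss_fn(self):
        if self.loss == "asl":
            return lambda p, y: asl(p, y, self.loss_params)
        if self.loss == "bce":
            return lambda p, y: bce(p, y)
        if self.loss == "focal":
            return lambda p, y: focal(p, y, self.focal_gamma)
        raise ValueError(f"unknown loss {self.loss!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["loss_params"] = asdict(self.loss_params)
        return d


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    test_micro_f1: list[float | None] = field(default_factory=list)
    stop_reason: str = ""
    best_epoch: int = -1

    def save_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("epoch\tloss\tlr\ttest_micro_f1\n")
            for e, (l, r, f1) in enumerate(zip(self.loss, self.lr,
                                               self.test_micro_f1), start=1):
                fh.write(f"{e}\t{l:.8f}\t{r:.8f}\t"
                         f"{'' if f1 is None else f'{f1:.6f}'}\n")


@dataclass
class Checkpoint:
    model_config: ModelConfig
    state: dict[str, np.ndarray]
    train_config: TrainConfig | None = None
    best_loss: float = float("inf")

    def build_model(self) -> EdgeClassifier:
        model = EdgeClassifier(self.model_config)
        model.load_state_dict(self.state)
        return model

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {"model_config": self.model_config.to_dict(),
                "train_config": (self.train_config.to_dict()
                                 if self.train_config else None),
                "best_loss": self.best_loss}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.state)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            state = {k: npz[k] for k in npz.files if k != "__meta__"}
        tc = meta.get("train_config")
        if tc is not None:
            tc = TrainConfig(**{**tc, "loss_params": ASLParams(**tc["loss_params"])})
        return cls(model_config=ModelConfig(**meta["model_config"]),
                   state=state, train_config=tc,
                   best_loss=meta.get("best_loss", float("inf")))


def _graph_arrays(graph: ProteinGraph, split: EdgeSplit, model_config: ModelConfig,
                  inductive: bool):
    subset = split.train_idx if inductive else None
    edge_index = edge_index_from_graph(graph, subset)
    ego = None
    if model_config.mode in ("combined", "local"):
        mp_graph = graph
        if inductive:
            mp_graph = ProteinGraph(protein_ids=list(graph.protein_ids),
                                    edges=graph.edges[split.train_idx],
                                    labels=graph.labels[split.train_idx],
                                    categories=graph.categories,
                                    features=graph.features)
        ego = egonet_batch(mp_graph, max(model_config.k, 1))
    return edge_index, ego


def train(graph: ProteinGraph, split: EdgeSplit, model_config: ModelConfig,
          train_config: TrainConfig) -> tuple[Checkpoint, TrainHistory]:
    """Adam on shuffled train-edge mini-batches; returns the best-loss
    checkpoint and the per-epoch history."""
    if graph.features is None:
        raise ValueError("graph has no features; attach features before training")
    split.validate(graph.n_edges)
    if model_config.input_dim != graph.features.shape[1]:
        raise ValueError("model input_dim does not match graph feature dim")

    model = EdgeClassifier(model_config)
    optimizer = Adam(model.parameters(), lr=train_config.lr)
    loss_fn = train_config.loss_fn()
    rng = np.random.default_rng(train_config.seed)
    edge_index, ego = _graph_arrays(graph, split, model_config,
                                    train_config.inductive)
    X = graph.features
    train_edges = split.train_idx.copy()
    history = TrainHistory()
    best_loss = float("inf")
    best_state = model.state_dict()
    best_epoch = 0
    stall = 0
    stall_decay = 0
    lr = train_config.lr

    for epoch in range(1, train_config.epochs + 1):
        model.train()
        order = rng.permutation(train_edges)
        epoch_losses = []
        for start in range(0, order.size, train_config.batch_size):
            batch = order[start:start + train_config.batch_size]
            probs = model(X, edge_index, ego, graph.edges[batch])
            loss = loss_fn(probs, graph.labels[batch].astype(np.float64))
            if not np.isfinite(loss.data):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch} "
                    f"(lr={lr}, batch_size={batch.size})")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
        epoch_loss = float(np.mean(epoch_losses))
        history.loss.append(epoch_loss)
        history.lr.append(lr)
        if train_config.eval_each_epoch:
            report = _evaluate_model(model, graph, split, edge_index, ego)
            history.test_micro_f1.append(report.primary_f1)
        else:
            history.test_micro_f1.append(None)

        if epoch_loss < best_loss - train_config.min_delta:
            best_loss = epoch_loss
            best_state = model.state_dict()
            best_epoch = epoch
            stall = 0
            stall_decay = 0
        else:
            stall += 1
            stall_decay += 1
            if stall >= train_config.patience:
                history.stop_reason = "early_stop"
                break
            if stall_decay >= max(train_config.patience // 2, 1):
                lr *= train_config.lr_decay
                optimizer.lr = lr
                stall_decay = 0
                logger.info("epoch %d: loss plateau, lr -> %g", epoch, lr)
    else:
        history.stop_reason = "max_epochs"
    history.best_epoch = best_epoch

    checkpoint = Checkpoint(model_config=model_config, state=best_state,
                            train_config=train_config, best_loss=best_loss)
    return checkpoint, history


def _evaluate_model(model: EdgeClassifier, graph: ProteinGraph,
                    split: EdgeSplit, edge_index, ego,
                    on: str = "test") -> MetricsReport:
    idx = split.test_idx if on == "test" else split.train_idx
    if idx.size == 0:
        raise ValueError(f"{on} split is empty")
    model.eval()
    probs = model(graph.features, edge_index, ego, graph.edges[idx])
    pred = (probs.data >= THRESHOLD).astype(np.uint8)
    model.train()
    return compute_report(pred, graph.labels[idx], list(graph.categories.names))


def evaluate(checkpoint: Checkpoint, graph: ProteinGraph, split: EdgeSplit,
             on: str = "test") -> MetricsReport:
    """Deterministic eval-mode predictions at threshold 0.5."""
    if graph.features is None:
        raise ValueError("graph has no features")
    if checkpoint.model_config.input_dim != graph.features.shape[1]:
        raise ValueError("checkpoint input_dim does not match graph features")
    model = checkpoint.build_model()
    inductive = bool(checkpoint.train_config and checkpoint.train_config.inductive)
    edge_index, ego = _graph_arrays(graph, split, checkpoint.model_config,
                                    inductive)
    report = _evaluate_model(model, graph, split, edge_index, ego, on=on)
    return report


def export_embeddings(checkpoint: Checkpoint, graph: ProteinGraph,
                      path: str | Path, split: EdgeSplit | None = None) -> None:
    """Write fused vertex embeddings (and per-edge product features with
    labels) for external visualization."""
    if graph.features is None:
        raise ValueError("graph has no features")
    model = checkpoint.build_model().eval()
    edge_index = edge_index_from_graph(graph)
    ego = None
    if checkpoint.model_config.mode in ("combined", "local"):
        ego = egonet_batch(graph, max(checkpoint.model_config.k, 1))
    H = model.vertex_embeddings(graph.features, edge_index, ego).data
    path = Path(path)
    with path.open("w") as fh:
        fh.write("protein_id\t" + "\t".join(f"h{i}" for i in range(H.shape[1]))
                 + "\n")
        for pid, row in zip(graph.protein_ids, H):
            fh.write(pid + "\t" + "\t".join(f"{x:.8g}" for x in row) + "\n")
    edge_path = path.with_name(path.stem + "_edges" + path.suffix)
    with edge_path.open("w") as fh:
        fh.write("id_a\tid_b\t"
                 + "\t".join(f"e{i}" for i in range(H.shape[1])) + "\t"
                 + "\t".join(graph.categories.names) + "\n")
        for (i, j), y in zip(graph.edges, graph.labels):
            prod = H[int(i)] * H[int(j)]
            fh.write(graph.protein_ids[int(i)] + "\t" + graph.protein_ids[int(j)]
                     + "\t" + "\t".join(f"{x:.8g}" for x in prod)
                     + "\t" + "\t".join(str(int(v)) for v in y) + "\n")
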