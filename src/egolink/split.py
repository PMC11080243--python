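"""Train/test edge partitions: uniform random, and BFS/DFS traversals that
concentrate test edges around traversal-discovered proteins (the unseen-
protein evaluation regime).

Traversal splits pick a random root and walk the graph; each time a protein
is taken from the queue/stack, its not-yet-assigned incident edges join the
test set (config flag `assign="visited-pair"` switches to the stricter rule
that only edges between two already-visited proteins are assigned). The
final dequeue may overshoot the target; the overshoot is kept and recorded
in the split metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph import ProteinGraph

logger = logging.getLogger(__name__)

SCHEMES = ("random", "bfs", "dfs")

__all__ = ["EdgeSplit", "random_split", "bfs_split", "dfs_split", "make_split"]


@dataclass
class EdgeSplit:
    scheme: str
    test_fraction: float
    seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=np.intp)
        self.test_idx = np.asarray(self.test_idx, dtype=np.intp)

    def validate(self, n_edges: int) -> None:
        train, test = set(self.train_idx.tolist()), set(self.test_idx.tolist())
        if train & test:
            raise ValueError("train/test edge sets overlap")
        if train | test != set(range(n_edges)):
            raise ValueError("split does not cover all edges exactly once")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# scheme={self.scheme}\tfraction={self.test_fraction}"
                     f"\tseed={self.seed}\n")
            fh.write("edge_index\tsubset\n")
            for e in self.train_idx:
                fh.write(f"{int(e)}\ttrain\n")
            for e in self.test_idx:
                fh.write(f"{int(e)}\ttest\n")

    @classmethod
    def load(cls, path: str | Path) -> "EdgeSplit":
        path = Path(path)
        lines = path.read_text().splitlines()
        meta = {}
        if lines and lines[0].startswith("#"):
            for kv in lines[0][1:].strip().split("\t"):
                k, v = kv.split("=", 1)
                meta[k] = v
        train, test = [], []
        for line in lines[1:]:
            if not line or line.startswith("edge_index"):
                continue
            idx, subset = line.split("\t")
            (test if subset == "test" else train).append(int(idx))
        return cls(scheme=meta.get("scheme", "unknown"),
                   test_fraction=float(meta.get("fraction", "nan")),
                   seed=int(meta.get("seed", 0)),
                   train_idx=np.array(sorted(train), dtype=np.intp),
                   test_idx=np.array(sorted(test), dtype=np.intp))


def _target_size(n_edges: int, test_fraction: float) -> int:
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    target = int(round(n_edges * test_fraction))
    if target < 1:
        raise ValueError("test_fraction too small: would yield an empty test set")
    return target


def _coverage_warning(graph: ProteinGraph, test_idx: np.ndarray) -> None:
    covered = graph.labels[test_idx].sum(axis=0)
    for c, name in enumerate(graph.categories.names):
        if covered[c] == 0:
            logger.warning("category %r has zero test edges", name)


def random_split(graph: ProteinGraph, test_fraction: float = 0.2,
                 seed: int = 0) -> EdgeSplit:
    """Uniform edge sample without replacement of size round(E * fraction)."""
    e = graph.n_edges
    target = _target_size(e, test_fraction)
    rng = np.random.default_rng(seed)
    test = np.sort(rng.choice(e, size=target, replace=False))
    mask = np.ones(e, dtype=bool)
    mask[test] = False
    split = EdgeSplit("random", test_fraction, seed,
                      train_idx=np.flatnonzero(mask), test_idx=test)
    split.validate(e)
    _coverage_warning(graph, split.test_idx)
    return split


def _traversal_split(graph: ProteinGraph, test_fraction: float, seed: int,
                     scheme: str, assign: str) -> EdgeSplit:
    e = graph.n_edges
    target = _target_size(e, test_fraction)
    rng = np.random.default_rng(seed)
    adj = graph.adjacency_lists()
    inc = graph.incident_edges()
    n = graph.n_proteins
    edge_assigned = np.zeros(e, dtype=bool)
    visited = np.zeros(n, dtype=bool)
    test: list[int] = []
    roots: list[int] = []

    def take_vertex(v: int) -> None:
        for eidx in inc[v]:
            eidx = int(eidx)
            if edge_assigned[eidx]:
                continue
            if assign == "visited-pair":
                i, j = graph.edges[eidx]
                other = int(j) if int(i) == v else int(i)
                if not visited[other]:
                    continue
            edge_assigned[eidx] = True
            test.append(eidx)

    while len(test) < target:
        unvisited = np.flatnonzero(~visited)
        if unvisited.size == 0:
            break
        root = int(rng.choice(unvisited))
        roots.append(root)
        if len(roots) > 1:
            logger.info("%s traversal exhausted a component; restarting at %d",
                        scheme, root)
        frontier: list[int] = [root]
        visited[root] = True
        while frontier and len(test) < target:
            v = frontier.pop(0) if scheme == "bfs" else frontier.pop()
            take_vertex(v)
            for w in adj[v]:
                w = int(w)
                if not visited[w]:
                    visited[w] = True
                    frontier.append(w)
    mask = np.ones(e, dtype=bool)
    mask[np.array(test, dtype=np.intp)] = False
    split = EdgeSplit(scheme, test_fraction, seed,
                      train_idx=np.flatnonzero(mask),
                      test_idx=np.array(sorted(test), dtype=np.intp),
                      metadata={"target": target, "overshoot": len(test) - target,
                                "roots": roots, "assign": assign})
    split.validate(e)
    _coverage_warning(graph, split.test_idx)
    return split


def bfs_split(graph: ProteinGraph, test_fraction: float = 0.2, seed: int = 0,
              assign: str = "incident") -> EdgeSplit:
    """Breadth-first traversal split (queue)."""
    return _traversal_split(graph, test_fraction, seed, "bfs", assign)


def dfs_split(graph: ProteinGraph, test_fraction: float = 0.2, seed: int = 0,
              assign: str = "incident") -> EdgeSplit:
    """Depth-first traversal split (stack)."""
    return _traversal_split(graph, test_fraction, seed, "dfs", assign)


def make_split(graph: ProteinGraph, scheme: str, test_fraction: float = 0.2,
               seed: int = 0) -> EdgeSplit:
    if scheme == "random":
        return random_split(graph, test_fraction, seed)
    if scheme == "bfs":
        return bfs_split(graph, test_fraction, seed)
    if scheme == "dfs":
        return dfs_split(graph, test_fraction, seed)
    raise ValueError(f"unknown split scheme {scheme!r}")
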