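"""k-hop egonet extraction and intra-subgraph hop distances.

Each vertex's egonet is the subgraph induced by all vertices within k hops
of it. Pairwise hop distances are computed *within* the induced subgraph
(not the full graph): the distance gates must reflect the subgraph the
kernel encoder actually sees. Members are ordered center first, then by
ascending vertex index, so batch layouts are deterministic.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .graph import ProteinGraph

__all__ = ["Egonet", "EgonetBatch", "extract_egonet", "distance_matrix",
           "egonet_batch"]


@dataclass
class Egonet:
    center: int
    members: np.ndarray          # ordered vertex indices, center first
    induced_edges: np.ndarray    # (m, 2) local member-position pairs
    dist_to_center: np.ndarray   # hops, aligned with members
    k: int
    _dist_matrix: np.ndarray | None = field(default=None, repr=False)

    @property
    def size(self) -> int:
        return int(self.members.shape[0])


def _bfs_from(source_pos: int, nbrs: list[list[int]], n: int) -> np.ndarray:
    dist = np.full(n, -1, dtype=np.int64)
    dist[source_pos] = 0
    q = deque([source_pos])
    while q:
        u = q.popleft()
        for w in nbrs[u]:
            if dist[w] < 0:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist


def extract_egonet(graph: ProteinGraph, v: int, k: int,
                   adjacency: list[np.ndarray] | None = None) -> Egonet:
    """Breadth-first expansion to depth k from v plus the induced edge set."""
    if not 0 <= v < graph.n_proteins:
        raise IndexError(f"vertex index {v} out of range")
    if k < 0:
        raise ValueError("hop radius k must be >= 0")
    adj = adjacency if adjacency is not None else graph.adjacency_lists()
    dist = {v: 0}
    frontier = [v]
    for hop in range(1, k + 1):
        nxt = []
        for u in frontier:
            for w in adj[u]:
                w = int(w)
                if w not in dist:
                    dist[w] = hop
                    nxt.append(w)
        frontier = nxt
    others = sorted(u for u in dist if u != v)
    members = np.array([v] + others, dtype=np.intp)
    pos = {int(u): p for p, u in enumerate(members)}
    member_set = set(pos)
    induced = []
    for p, u in enumerate(members):
        for w in adj[int(u)]:
            w = int(w)
            if w in member_set and pos[w] > p:
                induced.append((p, pos[w]))
    return Egonet(center=v,
                  members=members,
                  induced_edges=np.array(induced, dtype=np.intp).reshape(-1, 2),
                  dist_to_center=np.array([dist[int(u)] for u in members],
                                          dtype=np.int64),
                  k=k)


def distance_matrix(egonet: Egonet) -> np.ndarray:
    """Pairwise shortest-path hops within the induced subgraph.

    Every pair is connected through the center, so entries are <= 2k.
    """
    if egonet._dist_matrix is not None:
        return egonet._dist_matrix
    m = egonet.size
    nbrs: list[list[int]] = [[] for _ in range(m)]
    for a, b in egonet.induced_edges:
        nbrs[int(a)].append(int(b))
        nbrs[int(b)].append(int(a))
    D = np.empty((m, m), dtype=np.int64)
    for s in range(m):
        D[s] = _bfs_from(s, nbrs, m)
    egonet._dist_matrix = D
    return D


@dataclass
class EgonetBatch:
    """Disjoint-union layout of all n egonets for one shared encoder pass.

    Slot s in the flat layout belongs to egonet `slot_center[s]` and carries
    vertex `slot_vertex[s]`; `center_slot[v]` is the slot holding v inside
    its own egonet. `union_edges` are undirected slot pairs over the union.
    """

    k: int
    egonets: list[Egonet]
    slot_vertex: np.ndarray      # (M,) global vertex id per slot
    slot_center: np.ndarray      # (M,) center vertex id per slot
    slot_dist: np.ndarray        # (M,) hop distance of slot vertex to center
    center_slot: np.ndarray      # (n,) slot of each center within its egonet
    offsets: np.ndarray          # (n+1,) slot ranges per egonet
    union_edges: np.ndarray      # (m, 2) slot pairs

    @property
    def total_slots(self) -> int:
        return int(self.slot_vertex.shape[0])


def egonet_batch(graph: ProteinGraph, k: int,
                 max_total_members: int = 5_000_000) -> EgonetBatch:
    """Extract every vertex's k-hop egonet into one flat batch.

    Refuses to build batches whose disjoint union exceeds
    `max_total_members` slots (advice: use a smaller k).
    """
    if k < 1:
        raise ValueError("egonet_batch requires k >= 1")
    adj = graph.adjacency_lists()
    egonets: list[Egonet] = []
    total = 0
    for v in range(graph.n_proteins):
        ego = extract_egonet(graph, v, k, adjacency=adj)
        total += ego.size
        if total > max_total_members:
            raise MemoryError(
                f"egonet batch would exceed {max_total_members} member slots; "
                "use a smaller hop radius k")
        egonets.append(ego)
    offsets = np.zeros(graph.n_proteins + 1, dtype=np.intp)
    for v, ego in enumerate(egonets):
        offsets[v + 1] = offsets[v] + ego.size
    slot_vertex = np.concatenate([e.members for e in egonets]) if egonets else \
        np.zeros(0, dtype=np.intp)
    slot_center = np.concatenate(
        [np.full(e.size, e.center, dtype=np.intp) for e in egonets])
    slot_dist = np.concatenate([e.dist_to_center for e in egonets])
    center_slot = offsets[:-1].copy()   # center is always the first member
    union_parts = [e.induced_edges + offsets[v]
                   for v, e in enumerate(egonets) if e.induced_edges.size]
    union_edges = (np.concatenate(union_parts)
                   if union_parts else np.zeros((0, 2), dtype=np.intp))
    return EgonetBatch(k=k, egonets=egonets, slot_vertex=slot_vertex,
                       slot_center=slot_center, slot_dist=slot_dist,
                       center_slot=center_slot, offsets=offsets,
                       union_edges=union_edges)
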