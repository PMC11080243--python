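"""Canonical in-memory PPI graph plus parsers for interaction/feature tables.

The interaction format is a STRING-actions-like table with (at least) three
columns: id_a, id_b, mode. Tab or comma separated, header optional; both are
detected from the first line. Edges are undirected and multi-label: multiple
modes for the same protein pair are OR-ed into a single E x t binary row.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_CATEGORY_NAMES = (
    "Reaction", "Binding", "Ptmod", "Activation", "Inhibition",
    "Catalysis", "Expression",
)

__all__ = [
    "CategorySpace", "ProteinGraph", "read_interactions", "write_interactions",
    "attach_features", "category_statistics", "occupation_ratios",
    "DEFAULT_CATEGORY_NAMES",
]


@dataclass(frozen=True)
class CategorySpace:
    """Ordered label space for interaction modes."""

    names: tuple[str, ...] = DEFAULT_CATEGORY_NAMES

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ValueError("category space must be non-empty")
        if len(set(n.lower() for n in self.names)) != len(self.names):
            raise ValueError("category names must be unique (case-insensitive)")
        if any(not n for n in self.names):
            raise ValueError("category names must be non-empty strings")

    @property
    def t(self) -> int:
        return len(self.names)

    def index(self, mode: str) -> int:
        """Case-insensitive lookup; raises KeyError for unknown modes."""
        lowered = mode.strip().lower()
        for i, name in enumerate(self.names):
            if name.lower() == lowered:
                return i
        raise KeyError(mode)


@dataclass
class ProteinGraph:
    """Undirected multi-label interaction graph.

    edges are stored as (i, j) index pairs with i < j, in first-appearance
    order; labels is the E x t binary matrix; features (n x d) may be absent
    until :func:`attach_features` is called.
    """

    protein_ids: list[str]
    edges: np.ndarray            # (E, 2) intp, i < j
    labels: np.ndarray           # (E, t) uint8
    categories: CategorySpace = field(default_factory=CategorySpace)
    features: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.intp).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=np.uint8).reshape(
            -1, self.categories.t)
        self.validate()

    # -- basic accessors --------------------------------------------------

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def validate(self) -> None:
        n, e = self.n_proteins, self.n_edges
        if e != self.labels.shape[0]:
            raise ValueError("labels row count must equal edge count")
        if e:
            if self.edges.min() < 0 or self.edges.max() >= n:
                raise ValueError("edge index out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-loops are not allowed")
            lo = np.minimum(self.edges[:, 0], self.edges[:, 1])
            hi = np.maximum(self.edges[:, 0], self.edges[:, 1])
            self.edges = np.column_stack([lo, hi])
            if len({(int(a), int(b)) for a, b in self.edges}) != e:
                raise ValueError("duplicate undirected edges")
            if np.any(self.labels.sum(axis=1) == 0):
                raise ValueError("every edge must carry at least one category")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=np.float64)
            if self.features.shape[0] != n:
                raise ValueError("feature matrix must have one row per protein")
            if not np.all(np.isfinite(self.features)):
                raise ValueError("features must be finite")

    def adjacency_lists(self) -> list[np.ndarray]:
        """Sorted neighbor arrays per vertex."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_proteins)]
        for i, j in self.edges:
            nbrs[i].append(int(j))
            nbrs[j].append(int(i))
        return [np.array(sorted(a), dtype=np.intp) for a in nbrs]

    def incident_edges(self) -> list[np.ndarray]:
        """Edge-index lists per vertex (sorted by edge index)."""
        inc: list[list[int]] = [[] for _ in range(self.n_proteins)]
        for e, (i, j) in enumerate(self.edges):
            inc[int(i)].append(e)
            inc[int(j)].append(e)
        return [np.array(a, dtype=np.intp) for a in inc]

    def with_features(self, features: np.ndarray) -> "ProteinGraph":
        return replace(self, features=np.asarray(features, dtype=np.float64))


def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def read_interactions(path: str | Path,
                      categories: CategorySpace | None = None) -> ProteinGraph:
    """Parse an interaction table into a :class:`ProteinGraph`.

    Proteins are indexed in first-appearance order; (a, b) and (b, a) rows
    are merged; duplicate (pair, mode) rows collapse; self-interactions are
    skipped with a warning; an unknown mode is a hard error naming the line.
    """
    categories = categories or CategorySpace()
    path = Path(path)
    text = path.read_text().splitlines()
    index: dict[str, int] = {}
    pair_rows: dict[tuple[int, int], int] = {}
    edges: list[tuple[int, int]] = []
    rows: list[np.ndarray] = []
    delim = None
    for lineno, line in enumerate(text, start=1):
        if not line.strip():
            continue
        if delim is None:
            delim = _sniff_delimiter(line)
        parts = [p.strip() for p in line.split(delim)]
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected >= 3 columns, got {len(parts)}")
        a, b, mode = parts[0], parts[1], parts[2]
        try:
            c = categories.index(mode)
        except KeyError:
            if lineno == 1:
                # treat an unparseable first line as a header
                continue
            raise ValueError(
                f"{path}:{lineno}: unknown interaction mode {mode!r}") from None
        if a == b:
            logger.warning("%s:%d: skipping self-interaction for %r", path, lineno, a)
            continue
        for pid in (a, b):
            if pid not in index:
                index[pid] = len(index)
        i, j = index[a], index[b]
        key = (min(i, j), max(i, j))
        if key not in pair_rows:
            pair_rows[key] = len(edges)
            edges.append(key)
            rows.append(np.zeros(categories.t, dtype=np.uint8))
        rows[pair_rows[key]][c] = 1
    if not edges:
        raise ValueError(f"no interactions parsed from {path}")
    protein_ids = list(index.keys())
    return ProteinGraph(protein_ids=protein_ids,
                        edges=np.array(edges, dtype=np.intp),
                        labels=np.stack(rows),
                        categories=categories)


def write_interactions(graph: ProteinGraph, path: str | Path,
                       header: bool = True) -> None:
    """Write one (id_a, id_b, mode) TSV row per edge-label assignment."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if header:
            writer.writerow(["item_id_a", "item_id_b", "mode"])
        for (i, j), row in zip(graph.edges, graph.labels):
            for c in np.flatnonzero(row):
                writer.writerow([graph.protein_ids[int(i)],
                                 graph.protein_ids[int(j)],
                                 graph.categories.names[int(c)].lower()])


def _read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    first = path.read_text().splitlines()[0]
    delim = _sniff_delimiter(first)
    fields = first.split(delim)
    has_header = False
    if len(fields) >= 2:
        try:
            float(fields[1])
        except ValueError:
            has_header = True
    df = pd.read_csv(path, sep=delim, header=0 if has_header else None,
                     index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"feature table {path} has no feature columns")
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise ValueError(f"feature table {path} contains non-numeric entries")
    return df.astype(np.float64)


def attach_features(graph: ProteinGraph, table: str | Path) -> ProteinGraph:
    """Attach per-protein feature vectors, re-ordered to match the graph.

    Missing proteins are a hard error (all missing IDs listed); extra table
    rows are ignored with a warning.
    """
    df = _read_feature_table(table)
    df.index = df.index.astype(str)
    missing = [pid for pid in graph.protein_ids if pid not in df.index]
    if missing:
        raise ValueError(
            f"feature table is missing {len(missing)} protein(s): "
            + ", ".join(missing[:20]))
    extra = set(df.index) - set(graph.protein_ids)
    if extra:
        logger.warning("feature table has %d extra protein(s), ignored", len(extra))
    X = df.loc[graph.protein_ids].to_numpy()
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains non-finite values")
    return graph.with_features(X)


def occupation_ratios(counts: np.ndarray) -> np.ndarray:
    """Per-category share of all edge-label assignments (sums to 1)."""
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("no label assignments")
    return counts / total


def category_statistics(graph: ProteinGraph) -> pd.DataFrame:
    """Per-category sample count and occupation ratio.

    The ratio denominator is the total number of label assignments across
    all categories (an edge with two labels contributes twice), so the
    ratios sum to 1.
    """
    if graph.n_edges == 0:
        raise ValueError("graph has no edges")
    counts = graph.labels.sum(axis=0).astype(np.int64)
    ratios = occupation_ratios(counts)
    return pd.DataFrame({"count": counts, "ratio": ratios},
                        index=list(graph.categories.names))
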