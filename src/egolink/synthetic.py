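"""Seeded generator of PPI-like multi-label graphs with planted structure.

Vertices belong to latent functional groups; edges follow a stochastic
block model; every edge carries exactly one "primary" category determined
(up to a configurable confusion probability) by its group pair, plus
optional secondary categories, so each edge has at least one label and the
category signal is learnable from features (group centroid + noise).

When `imbalance_target` is set and no explicit rule is given, group pairs
are greedily assigned primary categories so the expected share of label
assignments per category tracks the target ratios.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .graph import CategorySpace, ProteinGraph, write_interactions

__all__ = ["SynthSpec", "GroundTruth", "generate", "easy_setting",
           "hard_setting", "write_fixture"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SynthSpec:
    n_proteins: int = 300
    n_groups: int = 6
    edge_prob_within: float = 0.12
    edge_prob_between: float = 0.03
    feature_dim: int = 32
    feature_noise_sd: float = 0.1
    n_categories: int = 7
    imbalance_target: tuple | None = None
    category_rule: np.ndarray | None = None   # (G, G, t) primary-category probs
    rule_confusion: float = 0.0               # prob of resampling the primary
    secondary_label_prob: float = 0.1         # extra labels per edge (per spare cat)
    deterministic_secondary: bool = False     # group-pair-derived second label
    degree_exponent: float | None = None      # power-law degree multiplier
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.edge_prob_within <= 1 and 0 <= self.edge_prob_between <= 1):
            raise ValueError("edge probabilities must be in [0, 1]")
        if self.imbalance_target is not None:
            t = np.asarray(self.imbalance_target, dtype=np.float64)
            if t.shape != (self.n_categories,) or np.any(t < 0):
                raise ValueError("imbalance_target must be nonnegative, length t")
            if abs(t.sum() - 1.0) > 1e-6:
                raise ValueError("imbalance_target must sum to 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["category_rule"] is not None:
            d["category_rule"] = np.asarray(d["category_rule"]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthSpec":
        d = dict(d)
        if d.get("category_rule") is not None:
            d["category_rule"] = np.asarray(d["category_rule"], dtype=np.float64)
        if d.get("imbalance_target") is not None:
            d["imbalance_target"] = tuple(d["imbalance_target"])
        return cls(**d)


@dataclass
class GroundTruth:
    groups: np.ndarray
    centroids: np.ndarray
    primary_rule: np.ndarray      # (G, G) primary category per group pair
    spec: SynthSpec


def _pair_masses(spec: SynthSpec, sizes: np.ndarray) -> dict[tuple[int, int], float]:
    masses = {}
    for a in range(spec.n_groups):
        for b in range(a, spec.n_groups):
            if a == b:
                masses[(a, b)] = spec.edge_prob_within * sizes[a] * (sizes[a] - 1) / 2
            else:
                masses[(a, b)] = spec.edge_prob_between * sizes[a] * sizes[b]
    return masses


def _build_primary_rule(spec: SynthSpec, sizes: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Greedy assignment of a primary category to each group pair so that
    expected edge mass per category approximates the target ratios."""
    t = spec.n_categories
    target = (np.asarray(spec.imbalance_target, dtype=np.float64)
              if spec.imbalance_target is not None
              else np.full(t, 1.0 / t))
    masses = _pair_masses(spec, sizes)
    total = sum(masses.values()) or 1.0
    assigned = np.zeros(t)
    rule = np.zeros((spec.n_groups, spec.n_groups), dtype=np.int64)
    # largest pairs first; each goes to the category furthest below target
    for (a, b), mass in sorted(masses.items(), key=lambda kv: -kv[1]):
        c = int(np.argmax(target - assigned))
        assigned[c] += mass / total
        rule[a, b] = rule[b, a] = c
    return rule


def generate(spec: SynthSpec) -> tuple[ProteinGraph, GroundTruth]:
    """Sample a graph with features; returns the graph and the planted truth."""
    rng = np.random.default_rng(spec.seed)
    n, g, t = spec.n_proteins, spec.n_groups, spec.n_categories
    groups = rng.integers(0, g, size=n)
    sizes = np.bincount(groups, minlength=g)

    # degree heterogeneity multiplier (optional)
    if spec.degree_exponent is not None:
        w = rng.pareto(spec.degree_exponent, size=n) + 1.0
        w = w / w.mean()
    else:
        w = np.ones(n)

    iu, ju = np.triu_indices(n, k=1)
    same = groups[iu] == groups[ju]
    p = np.where(same, spec.edge_prob_within, spec.edge_prob_between)
    p = np.clip(p * w[iu] * w[ju], 0.0, 1.0)
    keep = rng.random(p.shape) < p
    edges = np.column_stack([iu[keep], ju[keep]])
    if edges.shape[0] == 0:
        raise ValueError("degenerate spec: no edges sampled")

    primary_rule = (_build_primary_rule(spec, sizes, rng)
                    if spec.category_rule is None else None)
    labels = np.zeros((edges.shape[0], t), dtype=np.uint8)
    target = (np.asarray(spec.imbalance_target, dtype=np.float64)
              if spec.imbalance_target is not None else np.full(t, 1.0 / t))
    for e, (i, j) in enumerate(edges):
        a, b = int(groups[i]), int(groups[j])
        if spec.category_rule is not None:
            probs = np.asarray(spec.category_rule[a, b], dtype=np.float64)
            row = (rng.random(t) < probs).astype(np.uint8)
            if row.sum() == 0:
                row[int(np.argmax(probs))] = 1
            labels[e] = row
            continue
        c = int(primary_rule[a, b])
        if spec.rule_confusion > 0 and rng.random() < spec.rule_confusion:
            c = int(rng.choice(t, p=target / target.sum()))
        labels[e, c] = 1
        if spec.deterministic_secondary and a != b:
            # second label derived from the smaller group's within-group
            # category, so multi-label rows stay perfectly predictable
            labels[e, int(primary_rule[min(a, b), min(a, b)])] = 1
        if spec.secondary_label_prob > 0:
            extra = rng.random(t) < spec.secondary_label_prob * target * t
            labels[e] |= extra.astype(np.uint8)

    centroids = rng.normal(0.0, 1.0, size=(g, spec.feature_dim)) * 3.0
    X = centroids[groups] + rng.normal(0.0, spec.feature_noise_sd,
                                       size=(n, spec.feature_dim))
    names = CategorySpace().names[:t] if t <= 7 else tuple(
        f"C{i}" for i in range(t))
    graph = ProteinGraph(
        protein_ids=[f"P{i:05d}" for i in range(n)],
        edges=edges, labels=labels,
        categories=CategorySpace(names=tuple(names)), features=X)
    truth = GroundTruth(groups=groups, centroids=centroids,
                        primary_rule=(primary_rule if primary_rule is not None
                                      else np.full((g, g), -1)),
                        spec=spec)
    return graph, truth


TABLE_LIKE_TARGET = (0.18, 0.23, 0.08, 0.19, 0.08, 0.20, 0.04)


def easy_setting(seed: int = 0) -> SynthSpec:
    """Strong feature signal, deterministic category rule."""
    return SynthSpec(n_proteins=300, n_groups=6, edge_prob_within=0.12,
                     edge_prob_between=0.03, feature_dim=32,
                     feature_noise_sd=0.1, rule_confusion=0.0,
                     secondary_label_prob=0.0, deterministic_secondary=True,
                     seed=seed)


def hard_setting(seed: int = 0) -> SynthSpec:
    """Noisy, strongly imbalanced, overlapping category rules."""
    return SynthSpec(n_proteins=300, n_groups=6, edge_prob_within=0.12,
                     edge_prob_between=0.03, feature_dim=32,
                     feature_noise_sd=0.8, rule_confusion=0.15,
                     secondary_label_prob=0.05,
                     imbalance_target=(0.30, 0.25, 0.15, 0.12, 0.08, 0.06, 0.04),
                     seed=seed)


def _stub_sequence(protein_id: str, length: int = 60) -> str:
    """Deterministic pseudo-sequence derived from the protein id."""
    digest = hashlib.sha256(protein_id.encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def write_fixture(graph: ProteinGraph, out_dir: str | Path) -> dict[str, Path]:
    """Write interaction TSV + feature TSV + FASTA stub; round-trips through
    graph_io to an identical graph."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"interactions": out / "interactions.tsv",
             "features": out / "features.tsv",
             "fasta": out / "sequences.fasta"}
    write_interactions(graph, paths["interactions"])
    with paths["features"].open("w") as fh:
        d = 0 if graph.features is None else graph.features.shape[1]
        fh.write("protein_id\t" + "\t".join(f"f{i}" for i in range(d)) + "\n")
        for pid, row in zip(graph.protein_ids,
                            graph.features if graph.features is not None else []):
            fh.write(pid + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")
    with paths["fasta"].open("w") as fh:
        for pid in graph.protein_ids:
            fh.write(f">{pid}\n{_stub_sequence(pid)}\n")
    return paths
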