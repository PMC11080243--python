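"""Multi-label evaluation: per-category confusion counts, micro/macro/
weighted precision-recall-F1, and per-category accuracy (correct positives
divided by the category's test-set size, i.e. per-category recall).

Zero-division convention: 0/0 -> 0, with a logged warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["CategoryCounts", "MetricsReport", "confusion_counts", "prf",
           "per_category_accuracy", "compute_report"]


@dataclass(frozen=True)
class CategoryCounts:
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def support(self) -> np.ndarray:
        return self.tp + self.fn

    @property
    def t(self) -> int:
        return int(self.tp.shape[0])


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> CategoryCounts:
    """Cellwise TP/FP/FN/TN per category column."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = (pred & truth).sum(axis=0).astype(np.int64)
    fp = (pred & ~truth).sum(axis=0).astype(np.int64)
    fn = (~pred & truth).sum(axis=0).astype(np.int64)
    tn = (~pred & ~truth).sum(axis=0).astype(np.int64)
    return CategoryCounts(tp, fp, fn, tn)


def _safe_div(num, den, what: str):
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    if np.any(den == 0):
        logger.warning("0/0 in %s treated as 0", what)
    return np.divide(num, den, out=np.zeros_like(num + den), where=den != 0)


def prf(counts: CategoryCounts, averaging: str = "per-category"):
    """Precision, recall, F1 under the requested averaging.

    averaging: "per-category" (arrays), "micro" (pooled counts),
    "macro" (unweighted mean), "weighted" (support-weighted mean).
    """
    p = _safe_div(counts.tp, counts.tp + counts.fp, "precision")
    r = _safe_div(counts.tp, counts.tp + counts.fn, "recall")
    f1 = _safe_div(2 * p * r, p + r, "f1")
    if averaging == "per-category":
        return p, r, f1
    if averaging == "micro":
        tp, fp, fn = counts.tp.sum(), counts.fp.sum(), counts.fn.sum()
        mp = float(_safe_div(tp, tp + fp, "micro precision"))
        mr = float(_safe_div(tp, tp + fn, "micro recall"))
        mf = float(_safe_div(2 * mp * mr, mp + mr, "micro f1"))
        return mp, mr, mf
    if averaging == "macro":
        return float(p.mean()), float(r.mean()), float(f1.mean())
    if averaging == "weighted":
        w = counts.support.astype(np.float64)
        total = w.sum()
        if total == 0:
            logger.warning("no positive samples for weighted averaging")
            return 0.0, 0.0, 0.0
        w = w / total
        return float(p @ w), float(r @ w), float(f1 @ w)
    raise ValueError(f"unknown averaging {averaging!r}")


def per_category_accuracy(counts: CategoryCounts) -> np.ndarray:
    """TP_c / support_c; NaN (undefined) where support is zero."""
    support = counts.support.astype(np.float64)
    acc = np.full(counts.t, np.nan)
    nz = support > 0
    acc[nz] = counts.tp[nz] / support[nz]
    if not np.all(nz):
        logger.warning("%d categories have zero support; accuracy undefined",
                       int((~nz).sum()))
    return acc


@dataclass
class MetricsReport:
    category_names: list[str]
    counts: CategoryCounts
    per_category: dict = field(init=False)
    micro: tuple = field(init=False)
    macro: tuple = field(init=False)
    weighted: tuple = field(init=False)

    def __post_init__(self) -> None:
        p, r, f1 = prf(self.counts, "per-category")
        acc = per_category_accuracy(self.counts)
        self.per_category = {
            name: {"tp": int(self.counts.tp[c]), "fp": int(self.counts.fp[c]),
                   "fn": int(self.counts.fn[c]), "tn": int(self.counts.tn[c]),
                   "support": int(self.counts.support[c]),
                   "precision": float(p[c]), "recall": float(r[c]),
                   "f1": float(f1[c]),
                   "accuracy": None if np.isnan(acc[c]) else float(acc[c])}
            for c, name in enumerate(self.category_names)}
        self.micro = prf(self.counts, "micro")
        self.macro = prf(self.counts, "macro")
        self.weighted = prf(self.counts, "weighted")

    @property
    def primary_f1(self) -> float:
        """Headline metric: micro-F1."""
        return self.micro[2]

    def to_dict(self) -> dict:
        keys = ("precision", "recall", "f1")
        return {"per_category": self.per_category,
                "micro": dict(zip(keys, self.micro)),
                "macro": dict(zip(keys, self.macro)),
                "weighted": dict(zip(keys, self.weighted)),
                "primary_f1": self.primary_f1}

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def save_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("category\ttp\tfp\tfn\ttn\tsupport\tprecision\trecall"
                     "\tf1\taccuracy\n")
            for name, row in self.per_category.items():
                acc = "" if row["accuracy"] is None else f"{row['accuracy']:.6f}"
                fh.write(f"{name}\t{row['tp']}\t{row['fp']}\t{row['fn']}"
                         f"\t{row['tn']}\t{row['support']}"
                         f"\t{row['precision']:.6f}\t{row['recall']:.6f}"
                         f"\t{row['f1']:.6f}\t{acc}\n")


def compute_report(pred: np.ndarray, truth: np.ndarray,
                   category_names: list[str]) -> MetricsReport:
    return MetricsReport(list(category_names), confusion_counts(pred, truth))
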