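"""Asymmetric multi-label loss with focal and BCE as special cases.

Per-cell loss (y the binary target, p the predicted probability):

    L = -[ y * (1 - p)**g_pos * log(p)
           + (1 - y) * p_m**g_neg * log(1 - p_m) ],   p_m = max(p - m, 0)

with the convention 0**0 == 1. Setting g_pos = g_neg = gamma and m = 0
recovers focal loss; gamma = 0 recovers binary cross-entropy. Probabilities
are clamped to [eps, 1 - eps] (eps = 1e-8) before logs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = ["ASLParams", "asl", "focal", "bce"]

CLAMP_EPS = 1e-8


@dataclass(frozen=True)
class ASLParams:
    gamma_pos: float = 1.0
    gamma_neg: float = 0.0
    margin: float = 0.05

    def __post_init__(self) -> None:
        if self.gamma_pos < 0 or self.gamma_neg < 0:
            raise ValueError("focusing parameters must be >= 0")
        if not 0.0 <= self.margin < 1.0:
            raise ValueError("probability margin must be in [0, 1)")


def _reduce(cell: Tensor, reduction: str) -> Tensor:
    if reduction == "mean":
        return cell.mean()
    if reduction == "sum":
        return cell.sum()
    if reduction == "none":
        return cell
    raise ValueError(f"unknown reduction {reduction!r}")


def asl(probabilities, labels, params: ASLParams = ASLParams(),
        reduction: str = "mean"):
    """Asymmetric loss. Accepts ndarrays (returns float) or autodiff
    tensors (returns a Tensor on the computation graph)."""
    was_array = not isinstance(probabilities, Tensor)
    p = as_tensor(probabilities)
    y = np.asarray(labels.data if isinstance(labels, Tensor) else labels,
                   dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: probabilities {p.shape} vs labels {y.shape}")
    p = p.clamp(CLAMP_EPS, 1.0 - CLAMP_EPS)
    pm = (p - params.margin).relu()
    pos = ((1.0 - p) ** params.gamma_pos) * p.log()
    neg = (pm ** params.gamma_neg) * (1.0 - pm).clamp(CLAMP_EPS, 1.0).log()
    cell = -(y * pos + (1.0 - y) * neg)
    out = _reduce(cell, reduction)
    if was_array:
        return out.data if reduction == "none" else float(out.data)
    return out


def focal(probabilities, labels, gamma: float = 2.0, reduction: str = "mean"):
    """Focal loss: symmetric focusing, no probability margin."""
    return asl(probabilities, labels,
               ASLParams(gamma_pos=gamma, gamma_neg=gamma, margin=0.0),
               reduction=reduction)


def bce(probabilities, labels, reduction: str = "mean"):
    """Plain binary cross-entropy over all cells."""
    return asl(probabilities, labels,
               ASLParams(gamma_pos=0.0, gamma_neg=0.0, margin=0.0),
               reduction=reduction)
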