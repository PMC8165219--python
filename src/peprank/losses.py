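"""Ranking objectives: three pairwise hinge losses and a piecewise
mean-square loss.

All three hinge losses act on ordered pairs (i, j) of peptides sharing an
allele, scored S_i and S_j, and ask the score difference to exceed a
margin:

* value hinge  ``Hv = max(0, c + (b_i - b_j) - (S_i - S_j))`` for l_i > l_j
  — the margin grows with the affinity gap;
* level hinge  ``Hl = max(0, r*(l_i - l_j) - (S_i - S_j))`` for l_i > l_j
  — the margin depends only on the level gap;
* constrained level hinge ``Hi`` — equals Hl across levels, and within a
  level additionally caps the score spread: ``max(0, |S_i - S_j| - r)``.

The mean-square loss consumes sigmoid-normalized scores in (0, 1):
squared error for quantitative records, one-sided squared hinges toward
the level-threshold affinity for qualitative ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import MeasurementKind, level_threshold_b

LOSS_IDS = ("hv", "hl", "hi", "ms")

#: Hinge losses rank pairs across binding levels; hi also uses same-level
#: pairs; ms is pointwise.
PAIRWISE_LOSSES = ("hv", "hl", "hi")


class PairConstructionError(ValueError):
    pass


@dataclass(frozen=True)
class LossConfig:
    """Margin constants; c for the value hinge, r for the level hinges."""

    c: float = 0.2
    r: float = 0.2

    def __post_init__(self):
        if self.c <= 0 or self.r <= 0:
            raise ValueError("margin constants must be positive")


def hinge_value_loss(b_i, b_j, l_i, l_j, s_i, s_j, cfg: LossConfig = LossConfig()):
    """Value-based hinge; requires the first peptide on the higher level."""
    b_i, b_j, s_i, s_j = (np.asarray(v, dtype=float) for v in (b_i, b_j, s_i, s_j))
    if np.any(np.asarray(l_i) <= np.asarray(l_j)):
        raise PairConstructionError("value hinge needs l_i > l_j")
    out = np.maximum(0.0, cfg.c + (b_i - b_j) - (s_i - s_j))
    return float(out) if out.ndim == 0 else out


def hinge_level_loss(l_i, l_j, s_i, s_j, cfg: LossConfig = LossConfig()):
    """Level-based hinge; margin r per level of separation."""
    l_i = np.asarray(l_i, dtype=float)
    l_j = np.asarray(l_j, dtype=float)
    s_i = np.asarray(s_i, dtype=float)
    s_j = np.asarray(s_j, dtype=float)
    if np.any(l_i <= l_j):
        raise PairConstructionError("level hinge needs l_i > l_j")
    out = np.maximum(0.0, cfg.r * (l_i - l_j) - (s_i - s_j))
    return float(out) if out.ndim == 0 else out


def hinge_constrained_loss(l_i, l_j, s_i, s_j, cfg: LossConfig = LossConfig()):
    """Constrained level hinge: Hl across levels, score-spread cap within."""
    l_i = np.asarray(l_i, dtype=float)
    l_j = np.asarray(l_j, dtype=float)
    s_i = np.asarray(s_i, dtype=float)
    s_j = np.asarray(s_j, dtype=float)
    if np.any(l_i < l_j):
        raise PairConstructionError("constrained hinge needs l_i >= l_j")
    cross = np.maximum(0.0, cfg.r * (l_i - l_j) - (s_i - s_j))
    same = np.maximum(0.0, np.abs(s_i - s_j) - cfg.r)
    out = np.where(l_i > l_j, cross, same)
    return float(out) if out.ndim == 0 else out


def ms_target_b(b: float, level: int, kind: MeasurementKind) -> float:
    """Target affinity for the MS loss: measured b if quantitative, the
    level-threshold b otherwise."""
    if kind == MeasurementKind.QUANTITATIVE:
        return b
    return level_threshold_b(level)


def mean_square_loss(s, b, level, kind):
    """Piecewise MS loss on a sigmoid-normalized score s in (0, 1).

    Quantitative: (s-b)^2.  Qualitative negative (level 1): penalize only
    scores above the threshold; qualitative positive (level > 1): only
    scores below it.
    """
    s = float(s)
    if not (0.0 < s < 1.0):
        raise ValueError("MS loss expects a sigmoid-normalized score in (0,1)")
    if kind == MeasurementKind.QUANTITATIVE:
        return (s - b) ** 2
    target = level_threshold_b(level)
    if level == 1:
        return max(0.0, s - target) ** 2
    return max(0.0, target - s) ** 2


def pair_loss_and_score_grad(loss_id, b_i, b_j, l_i, l_j, s_i, s_j, cfg):
    """Vectorized per-pair loss and d(loss)/d(S_i), d(loss)/d(S_j).

    Hinge gradients are -1/+1 inside the margin and 0 outside; the same-
    level branch of ``hi`` uses the sign of the score gap.
    """
    b_i, b_j, s_i, s_j = (np.asarray(v, dtype=float) for v in (b_i, b_j, s_i, s_j))
    l_i = np.asarray(l_i, dtype=float)
    l_j = np.asarray(l_j, dtype=float)
    if loss_id == "hv":
        margin = cfg.c + (b_i - b_j)
        raw = margin - (s_i - s_j)
        loss = np.maximum(0.0, raw)
        active = (raw > 0).astype(float)
        return loss, -active, active
    if loss_id == "hl":
        raw = cfg.r * (l_i - l_j) - (s_i - s_j)
        loss = np.maximum(0.0, raw)
        active = (raw > 0).astype(float)
        return loss, -active, active
    if loss_id == "hi":
        cross_raw = cfg.r * (l_i - l_j) - (s_i - s_j)
        same_raw = np.abs(s_i - s_j) - cfg.r
        is_cross = l_i > l_j
        loss = np.where(is_cross, np.maximum(0.0, cross_raw), np.maximum(0.0, same_raw))
        cross_active = (cross_raw > 0).astype(float)
        same_active = (same_raw > 0).astype(float) * np.sign(s_i - s_j)
        g_i = np.where(is_cross, -cross_active, same_active)
        g_j = np.where(is_cross, cross_active, -same_active)
        return loss, g_i, g_j
    raise ValueError(f"not a pairwise loss: {loss_id}")


def ms_loss_and_score_grad(s, b_target, level, is_quantitative):
    """Vectorized MS loss and gradient w.r.t. the sigmoid score.

    ``b_target`` must already be the measured b (quantitative) or the
    level-threshold b (qualitative).
    """
    s = np.asarray(s, dtype=float)
    b_target = np.asarray(b_target, dtype=float)
    level = np.asarray(level)
    quant = np.asarray(is_quantitative, dtype=bool)
    diff = s - b_target
    neg_gate = (level == 1) & ~quant
    pos_gate = (level > 1) & ~quant
    eff = np.where(quant, diff, 0.0)
    eff = np.where(neg_gate, np.maximum(0.0, diff), eff)
    eff = np.where(pos_gate, np.minimum(0.0, diff), eff)
    return eff**2, 2.0 * eff
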