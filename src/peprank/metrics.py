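"""Ranking evaluation: average rank, hit rate, AUC, early-retrieval ROC_t,
and the hybrid model-selection metric H.

The promising set P_h contains peptides with IC50 strictly below h nM
(equivalently normalized affinity above the normalized threshold).  Ranks
are 1-based with 1 the highest score; ties are broken by input order with
a warning, since the definitions presume a total order.  AUC and ROC_t use
the strict indicator S_pos > S_neg — ties earn no credit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import normalize_affinity

logger = logging.getLogger(__name__)

#: The seven evaluation metrics; AR metrics are smaller-is-better.
METRIC_NAMES = ("AR100", "HR100", "AR500", "HR500", "AUC", "ROC5", "ROC10")
SMALLER_IS_BETTER = frozenset({"AR100", "AR500"})

POSITIVE_THRESHOLD_NM = 500.0


class UndefinedMetricError(ValueError):
    """Raised when a metric's preconditions (both classes present, enough
    negatives, non-empty promising set) are not met."""


@dataclass(frozen=True)
class RankedPredictions:
    """Scores with ground-truth normalized affinities (and levels)."""

    scores: np.ndarray
    b: np.ndarray
    levels: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        if len(self.scores) != len(self.b):
            raise ValueError("scores and affinities must align")

    def to_frame(self) -> pd.DataFrame:
        data = {"score": self.scores, "b": self.b}
        if self.levels is not None:
            data["level"] = self.levels
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RankedPredictions":
        levels = frame["level"].to_numpy() if "level" in frame else None
        return cls(frame["score"].to_numpy(), frame["b"].to_numpy(), levels)


def _as_arrays(scores, b):
    scores = np.asarray(scores, dtype=float)
    b = np.asarray(b, dtype=float)
    if scores.shape != b.shape or scores.ndim != 1:
        raise ValueError("scores and affinities must be 1-D and aligned")
    return scores, b


def promising_mask(b, h_nm: float) -> np.ndarray:
    """Membership in P_h: IC50 strictly below h nM."""
    return np.asarray(b, dtype=float) > normalize_affinity(h_nm)


def ranks_from_scores(scores) -> np.ndarray:
    """1-based ranks, 1 = highest score; ties keep input order (warned)."""
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(scores)) < len(scores):
        logger.warning("tied scores: ranks broken by input order")
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty(len(scores), dtype=np.intp)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


def average_rank(scores, b, h_nm: float) -> float:
    """AR_h: mean rank of the promising peptides (lower is better)."""
    scores, b = _as_arrays(scores, b)
    pos = promising_mask(b, h_nm)
    if not pos.any():
        raise UndefinedMetricError(f"no peptide below {h_nm} nM")
    return float(ranks_from_scores(scores)[pos].mean())


def hit_rate(scores, b, h_nm: float) -> float:
    """HR_h: fraction of P_h recovered in the top t = |P_h| ranks."""
    scores, b = _as_arrays(scores, b)
    pos = promising_mask(b, h_nm)
    t = int(pos.sum())
    if t == 0:
        raise UndefinedMetricError(f"no peptide below {h_nm} nM")
    in_top = ranks_from_scores(scores) <= t
    return float((in_top & pos).sum() / t)


def auc(scores, b, h_nm: float = POSITIVE_THRESHOLD_NM) -> float:
    """Pairwise AUC with the strict indicator (ties score zero)."""
    scores, b = _as_arrays(scores, b)
    pos = promising_mask(b, h_nm)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs both classes")
    wins = scores[pos][:, None] > scores[~pos][None, :]
    return float(wins.sum() / (n_pos * n_neg))


def roc_t(scores, b, t: int, h_nm: float = POSITIVE_THRESHOLD_NM) -> float:
    """ROC_t: positive-vs-negative wins against the t top-scoring
    negatives, normalized by |P_500| * t."""
    scores, b = _as_arrays(scores, b)
    pos = promising_mask(b, h_nm)
    n_pos = int(pos.sum())
    neg_scores = scores[~pos]
    if n_pos == 0:
        raise UndefinedMetricError("ROC_t needs at least one positive")
    if len(neg_scores) < t:
        raise UndefinedMetricError(f"ROC_t needs at least {t} negatives")
    top_neg = np.sort(neg_scores)[::-1][:t]
    wins = scores[pos][:, None] > top_neg[None, :]
    return float(wins.sum() / (n_pos * t))


def metric_report(scores, b) -> dict:
    """The seven metrics; undefined metrics are reported as NaN."""
    out = {}
    for name, fn in (
        ("AR100", lambda: average_rank(scores, b, 100.0)),
        ("HR100", lambda: hit_rate(scores, b, 100.0)),
        ("AR500", lambda: average_rank(scores, b, 500.0)),
        ("HR500", lambda: hit_rate(scores, b, 500.0)),
        ("AUC", lambda: auc(scores, b)),
        ("ROC5", lambda: roc_t(scores, b, 5)),
        ("ROC10", lambda: roc_t(scores, b, 10)),
    ):
        try:
            out[name] = fn()
        except UndefinedMetricError:
            out[name] = float("nan")
    return out


def hybrid_metric(values: dict, best: dict) -> float:
    """H for one configuration given the per-metric best over the grid.

    ``H = sum_mtrc I(down) * (mtrc - best) / best`` with I = +1 for
    smaller-is-better metrics (the AR family) and -1 otherwise, and best
    the best-performing value (min for AR, max for the rest).  H >= 0,
    attaining 0 only for a configuration best on every metric; model
    selection minimizes H.  Metrics with best == 0 are skipped.
    """
    total = 0.0
    for name, value in values.items():
        ref = best[name]
        if not np.isfinite(value) or not np.isfinite(ref):
            raise UndefinedMetricError(f"metric {name} undefined")
        if ref == 0:
            logger.warning("metric %s has zero best value; skipped in H", name)
            continue
        sign = 1.0 if name in SMALLER_IS_BETTER else -1.0
        total += sign * (value - ref) / ref
    return total


def best_per_metric(table: pd.DataFrame) -> dict:
    """Best-performing value per metric column over a grid table."""
    return {
        name: (table[name].min() if name in SMALLER_IS_BETTER else table[name].max())
        for name in table.columns
        if name in METRIC_NAMES
    }


def hybrid_scores(table: pd.DataFrame) -> pd.Series:
    """H per row of a (configurations x metrics) table."""
    best = best_per_metric(table)
    return table.apply(
        lambda row: hybrid_metric({m: row[m] for m in METRIC_NAMES}, best), axis=1
    )
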