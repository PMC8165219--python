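"""Pair-batch construction, the SGD schedule, and cross-validated grid
search.

Training batches are built by sampling a batch of peptides and drawing
ranking pairs inside it: for the value and level hinges every pair spans
two different binding levels (ordered so the first member is the higher
level); the constrained hinge also admits same-level pairs.  The schedule
is plain SGD from lr=0.05 with validation-driven decay (x0.9 after 5
epochs without improvement) and early stopping (20 epochs without
improvement); the parameters of the best-validation epoch are returned.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from .losses import (
    LossConfig,
    PAIRWISE_LOSSES,
    ms_loss_and_score_grad,
    ms_target_b,
    pair_loss_and_score_grad,
)
from .models import FeatureCache, ModelConfig, ModelState, forward, init_state
from .preprocessing import MeasurementKind, NormalizedEntry, denormalize_affinity

logger = logging.getLogger(__name__)


class NoValidPairsError(ValueError):
    """Raised when a hinge loss is asked to train on single-level data."""


class DivergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = 0.05
    lr_decay_patience: int = 5
    lr_decay_factor: float = 0.9
    early_stop_patience: int = 20
    validation_fraction: float = 0.10
    max_epochs: int = 150
    batch_size: int = 64
    #: ranking pairs drawn per batch; None means 8 * batch_size.  A single
    #: pair per batch peptide leaves the hinge gradient too noisy for the
    #: 0.05-lr schedule to make steady validation progress at small data
    #: sizes; eight pairs per peptide stabilizes the estimate at negligible
    #: cost (pair losses are score-space only).
    pairs_per_batch: int | None = None
    folds: int = 5
    loss_cfg: LossConfig = field(default_factory=LossConfig)
    #: relative improvement below which a validation loss does not count
    #: as a decrease (guards patience against float jitter)
    rel_tolerance: float = 1e-4

    def __post_init__(self):
        if self.lr_decay_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patiences must be >= 1")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation fraction must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")


class PlateauScheduler:
    """Learning-rate decay and early stopping driven by validation loss.

    ``step`` returns True while training should continue.  A loss counts
    as an improvement when it undercuts the running best by a relative
    margin; the learning rate decays every ``decay_patience`` stale epochs
    and training stops after ``stop_patience`` stale epochs.
    """

    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        self.lr = cfg.initial_lr
        self.best = np.inf
        self.stale = 0
        self.improved = False

    def step(self, val_loss: float) -> bool:
        if val_loss < self.best * (1.0 - self.cfg.rel_tolerance) or not np.isfinite(
            self.best
        ):
            self.best = val_loss
            self.stale = 0
            self.improved = True
            return True
        self.improved = False
        self.stale += 1
        if self.stale >= self.cfg.early_stop_patience:
            return False
        if self.stale % self.cfg.lr_decay_patience == 0:
            self.lr *= self.cfg.lr_decay_factor
        return True


def _entry_arrays(entries):
    peptides = [e.peptide for e in entries]
    b = np.array([e.b for e in entries])
    levels = np.array([e.level for e in entries])
    quant = np.array([e.kind == MeasurementKind.QUANTITATIVE for e in entries])
    return peptides, b, levels, quant


def _margin_b(entries) -> np.ndarray:
    """b used in margins/targets: threshold-imputed for qualitative."""
    return np.array(
        [ms_target_b(e.b, e.level, e.kind) for e in entries], dtype=float
    )


def sample_pair_batch(entries, loss_id, batch_size, rng, pairs_per_batch=None):
    """Sample a peptide batch and ranking pairs within it.

    Returns (member indices into ``entries``, pair index array of shape
    (n_pairs, 2) into ``entries``); for the MS loss the pair array is empty.
    """
    n = len(entries)
    take = min(batch_size, n)
    members = rng.choice(n, size=take, replace=False)
    if loss_id == "ms":
        return members, np.empty((0, 2), dtype=np.intp)
    if loss_id not in PAIRWISE_LOSSES:
        raise ValueError(f"unknown loss {loss_id!r}")
    levels = np.array([entries[i].level for i in members])
    if loss_id in ("hv", "hl") and len(set(e.level for e in entries)) < 2:
        raise NoValidPairsError("hinge losses need entries from >= 2 levels")
    n_pairs = pairs_per_batch or 8 * batch_size
    for _ in range(50):
        diff = levels[:, None] != levels[None, :]
        if loss_id == "hi":
            valid = np.argwhere(~np.eye(take, dtype=bool))
            # orient cross-level pairs higher-level-first; same-level pairs
            # are symmetric, keep one orientation
            keep = []
            for a, bdx in valid:
                if levels[a] > levels[bdx] or (
                    levels[a] == levels[bdx] and a < bdx
                ):
                    keep.append((a, bdx))
            valid = np.array(keep, dtype=np.intp)
        else:
            valid = np.argwhere(levels[:, None] > levels[None, :])
        if len(valid):
            chosen = valid[rng.integers(0, len(valid), size=n_pairs)]
            return members, members[chosen]
        members = rng.choice(n, size=take, replace=False)
        levels = np.array([entries[i].level for i in members])
    raise NoValidPairsError("could not sample a batch containing valid pairs")


def _validation_loss(state, entries, feats, cfg: TrainConfig):
    """Deterministic evaluation-mode loss over the validation set.

    Hinge losses average over every valid pair; MS averages over entries.
    """
    scores, _ = forward(state, feats, training=False)
    loss_id = state.config.loss_id
    _, b, levels, quant = _entry_arrays(entries)
    if loss_id == "ms":
        targets = _margin_b(entries)
        losses, _ = ms_loss_and_score_grad(scores, targets, levels, quant)
        return float(losses.mean())
    mb = _margin_b(entries)
    if loss_id == "hi":
        ii, jj = np.where(
            (levels[:, None] > levels[None, :])
            | (
                (levels[:, None] == levels[None, :])
                & (np.arange(len(levels))[:, None] < np.arange(len(levels))[None, :])
            )
        )
    else:
        ii, jj = np.where(levels[:, None] > levels[None, :])
    if len(ii) == 0:
        raise NoValidPairsError("validation split has no valid pairs")
    losses, _, _ = pair_loss_and_score_grad(
        loss_id, mb[ii], mb[jj], levels[ii], levels[jj], scores[ii], scores[jj],
        cfg.loss_cfg,
    )
    return float(losses.mean())


def train_model(
    entries,
    config: ModelConfig,
    train_cfg: TrainConfig,
    rng: np.random.Generator,
    validation_entries=None,
    feature_cache: FeatureCache | None = None,
):
    """Train one allele-specific model; returns (best ModelState, log).

    ``entries`` are consolidated records of one allele.  When no explicit
    validation set is given, a ``validation_fraction`` split is held out.
    The log is a list of per-epoch dicts (train/validation loss, lr).
    """
    entries = list(entries)
    if validation_entries is None:
        order = rng.permutation(len(entries))
        n_val = max(1, int(round(train_cfg.validation_fraction * len(entries))))
        val_idx = set(order[:n_val].tolist())
        validation_entries = [entries[i] for i in sorted(val_idx)]
        entries = [entries[i] for i in range(len(entries)) if i not in val_idx]
    if config.loss_id in ("hv", "hl"):
        if len({e.level for e in entries}) < 2:
            raise NoValidPairsError("training entries span a single level")

    fcache = feature_cache or FeatureCache()
    val_feats = fcache.get_many([e.peptide for e in validation_entries])
    train_peps, train_b, train_levels, train_quant = _entry_arrays(entries)
    train_mb = _margin_b(entries)
    train_feats = fcache.get_many(train_peps)

    state = init_state(config, rng)
    scheduler = PlateauScheduler(train_cfg)
    best_state = state.copy()
    log = []
    batches_per_epoch = max(1, len(entries) // max(1, train_cfg.batch_size))

    for epoch in range(train_cfg.max_epochs):
        epoch_loss = 0.0
        for _ in range(batches_per_epoch):
            members, pairs = sample_pair_batch(
                entries,
                config.loss_id,
                train_cfg.batch_size,
                rng,
                train_cfg.pairs_per_batch,
            )
            feats = [train_feats[i] for i in members]
            scores, cache = forward(state, feats, training=True)
            pos_in_batch = {g: i for i, g in enumerate(members)}
            if config.loss_id == "ms":
                losses, dldS = ms_loss_and_score_grad(
                    scores,
                    train_mb[members],
                    train_levels[members],
                    train_quant[members],
                )
                dscores = dldS / len(members)
                batch_loss = float(losses.mean())
            else:
                ii = pairs[:, 0]
                jj = pairs[:, 1]
                losses, g_i, g_j = pair_loss_and_score_grad(
                    config.loss_id,
                    train_mb[ii],
                    train_mb[jj],
                    train_levels[ii],
                    train_levels[jj],
                    scores[[pos_in_batch[g] for g in ii]],
                    scores[[pos_in_batch[g] for g in jj]],
                    train_cfg.loss_cfg,
                )
                dscores = np.zeros(len(members))
                for g, gi, gj in zip(pairs, g_i, g_j):
                    dscores[pos_in_batch[g[0]]] += gi
                    dscores[pos_in_batch[g[1]]] += gj
                dscores /= len(pairs)
                batch_loss = float(losses.mean())
            if not np.isfinite(batch_loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            grads = backward_and_update(state, cache, dscores, scheduler.lr)
            epoch_loss += batch_loss
        val_loss = _validation_loss(state, validation_entries, val_feats, train_cfg)
        if not np.isfinite(val_loss):
            raise DivergenceError(f"non-finite validation loss at epoch {epoch}")
        keep_going = scheduler.step(val_loss)
        if scheduler.improved:
            best_state = state.copy()
        log.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / batches_per_epoch,
                "val_loss": val_loss,
                "lr": scheduler.lr,
            }
        )
        if not keep_going:
            break
    return best_state, log


def backward_and_update(state, cache, dscores, lr):
    from .models import backward

    grads = backward(state, cache, dscores)
    for name, g in grads.items():
        state.params[name] -= lr * g
    return grads


# ---------------------------------------------------------------------------
# Cross-validated grid search


@dataclass(frozen=True)
class GridSpec:
    """Candidate lists per hyperparameter; unset fields keep defaults."""

    candidates: dict = field(default_factory=dict)
    selection_metric: str = "H"

    def points(self, base: ModelConfig):
        keys = sorted(self.candidates)
        for values in itertools.product(*(self.candidates[k] for k in keys)):
            yield replace(base, **dict(zip(keys, values)))


def kfold_by_peptide(entries, folds, rng):
    """Partition entries into folds by peptide, sizes differing by <= 1."""
    peptides = sorted({e.peptide for e in entries})
    order = rng.permutation(len(peptides))
    assignment = {}
    for pos, pi in enumerate(order):
        assignment[peptides[pi]] = pos % folds
    return [
        [e for e in entries if assignment[e.peptide] == f] for f in range(folds)
    ]


def evaluate_entries(state, entries, feature_cache=None):
    """The seven ranking metrics of a model on held-out entries."""
    from .models import score_peptides

    scores = score_peptides(state, [e.peptide for e in entries], feature_cache)
    b = np.array([e.b for e in entries])
    return metrics_mod.metric_report(scores, b)


def cross_validate_grid(entries, grid: GridSpec, train_cfg: TrainConfig,
                        base_config: ModelConfig, rng: np.random.Generator):
    """Grid search with peptide-level k-fold CV; selects by the hybrid
    metric H over fold-averaged metrics.

    Returns (best ModelConfig, tidy per-(config, fold) metric table).
    """
    entries = list(entries)
    folds = kfold_by_peptide(entries, train_cfg.folds, rng)
    fcache = FeatureCache()
    rows = []
    configs = list(grid.points(base_config))
    for ci, config in enumerate(configs):
        for f, test_fold in enumerate(folds):
            train_entries = [e for g, fold in enumerate(folds) if g != f for e in fold]
            child = np.random.default_rng(rng.integers(0, 2**31))
            state, _ = train_model(
                train_entries, config, train_cfg, child, feature_cache=fcache
            )
            report = evaluate_entries(state, test_fold, fcache)
            rows.append({"config_index": ci, "fold": f, **report})
    table = pd.DataFrame(rows)
    per_config = table.groupby("config_index")[list(metrics_mod.METRIC_NAMES)].mean()
    hybrid = metrics_mod.hybrid_scores(per_config)
    best_ci = int(hybrid.idxmin())
    table["H"] = table["config_index"].map(hybrid)
    return configs[best_ci], table
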