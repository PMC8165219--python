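"""Scikit-learn style estimators wrapping the ConvM/SpConvM trainers.

``ConvMRanker`` and ``SpConvMRanker`` follow the fit/predict contract:
``fit`` takes peptide sequences plus normalized affinities (and optional
binding levels/measurement kinds), ``predict`` returns ranking scores.
They compose with sklearn model selection and pipelines; the underlying
functional interface lives in :mod:`peprank.training`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .encoding import EncodingScheme
from .losses import LOSS_IDS, LossConfig
from .models import FeatureCache, ModelConfig, score_peptides, attention_weights
from .preprocessing import (
    MeasurementKind,
    NormalizedEntry,
    affinity_to_level,
    denormalize_affinity,
)
from .training import TrainConfig, train_model


def _as_entries(X, y, levels, kinds, allele="query"):
    if y is None and X and isinstance(X[0], NormalizedEntry):
        return list(X)
    if y is None:
        raise ValueError("y (normalized affinities) is required")
    peptides = list(X)
    b = np.asarray(y, dtype=float)
    if len(peptides) != len(b):
        raise ValueError("X and y must align")
    if np.any((b < 0) | (b > 1)):
        raise ValueError("normalized affinities must lie in [0, 1]")
    if levels is None:
        levels = [
            affinity_to_level(denormalize_affinity(min(max(v, 1e-9), 1 - 1e-9)))
            for v in b
        ]
    if kinds is None:
        kinds = [MeasurementKind.QUANTITATIVE] * len(peptides)
    return [
        NormalizedEntry(allele, p, float(v), int(l), MeasurementKind(k))
        for p, v, l, k in zip(peptides, b, levels, kinds)
    ]


class ConvMRanker(BaseEstimator, RegressorMixin):
    """Convolution + attention peptide ranking model (local kernels only).

    Parameters mirror the architecture hyperparameters: ``kernel_size``
    (k), ``n_filters`` (d_r), ``attention_units`` (d_a), ``position_dim``
    (d_o), plus the loss selection (``hv``/``hl``/``hi``/``ms``) with a
    shared margin constant, and the SGD schedule settings.
    """

    _architecture = "convm"

    def __init__(
        self,
        kernel_size: int = 1,
        n_filters: int = 16,
        attention_units: int = 8,
        position_dim: int = 4,
        encoding: str = "blosum",
        use_positions: bool = True,
        loss: str = "hv",
        margin: float = 0.2,
        learning_rate: float = 0.05,
        batch_size: int = 64,
        max_epochs: int = 150,
        validation_fraction: float = 0.1,
        random_state: int | None = None,
    ):
        self.kernel_size = kernel_size
        self.n_filters = n_filters
        self.attention_units = attention_units
        self.position_dim = position_dim
        self.encoding = encoding
        self.use_positions = use_positions
        self.loss = loss
        self.margin = margin
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- configuration -----------------------------------------------------

    def _model_config(self) -> ModelConfig:
        if self.loss not in LOSS_IDS:
            raise ValueError(f"unknown loss {self.loss!r}")
        extra = {}
        if self._architecture == "spconvm":
            extra["d_g"] = self.n_global_kernels
        return ModelConfig(
            architecture=self._architecture,
            k=self.kernel_size,
            d_r=self.n_filters,
            d_a=self.attention_units,
            d_o=self.position_dim,
            scheme=EncodingScheme.parse(self.encoding),
            use_positions=self.use_positions,
            loss_id=self.loss,
            **extra,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            initial_lr=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            validation_fraction=self.validation_fraction,
            loss_cfg=LossConfig(c=self.margin, r=self.margin),
        )

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None, levels=None, kinds=None):
        """Fit on peptides X and normalized affinities y in [0, 1].

        X may instead be a list of :class:`NormalizedEntry` (then y is
        omitted).  ``levels``/``kinds`` override the values derived from y.
        """
        entries = _as_entries(list(X), y, levels, kinds)
        rng = np.random.default_rng(self.random_state)
        self._feature_cache = FeatureCache()
        self.config_ = self._model_config()
        self.state_, self.history_ = train_model(
            entries,
            self.config_,
            self._train_config(),
            rng,
            feature_cache=self._feature_cache,
        )
        self.n_epochs_ = len(self.history_)
        self.validation_loss_ = min(h["val_loss"] for h in self.history_)
        return self

    def predict(self, X) -> np.ndarray:
        """Ranking scores; sigmoid-bounded in (0, 1) iff loss='ms'."""
        check_is_fitted(self, "state_")
        return score_peptides(self.state_, list(X), self._feature_cache)

    def score(self, X, y=None) -> float:
        """Held-out AUC at the 500 nM threshold (sklearn convention:
        larger is better)."""
        from .metrics import auc

        check_is_fitted(self, "state_")
        return auc(self.predict(X), np.asarray(y, dtype=float))

    def attention(self, X) -> list[np.ndarray]:
        """Per-peptide attention weight vectors (each sums to 1)."""
        check_is_fitted(self, "state_")
        return attention_weights(self.state_, list(X), self._feature_cache)

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.string = True
        tags.input_tags.two_d_array = False
        return tags


class SpConvMRanker(ConvMRanker):
    """ConvM plus d_g global kernels over the middle-padded 15-mer frame."""

    _architecture = "spconvm"

    def __init__(
        self,
        kernel_size: int = 1,
        n_filters: int = 16,
        attention_units: int = 8,
        position_dim: int = 4,
        n_global_kernels: int = 8,
        encoding: str = "blosum",
        use_positions: bool = True,
        loss: str = "hv",
        margin: float = 0.2,
        learning_rate: float = 0.05,
        batch_size: int = 64,
        max_epochs: int = 150,
        validation_fraction: float = 0.1,
        random_state: int | None = None,
    ):
        super().__init__(
            kernel_size=kernel_size,
            n_filters=n_filters,
            attention_units=attention_units,
            position_dim=position_dim,
            encoding=encoding,
            use_positions=use_positions,
            loss=loss,
            margin=margin,
            learning_rate=learning_rate,
            batch_size=batch_size,
            max_epochs=max_epochs,
            validation_fraction=validation_fraction,
            random_state=random_state,
        )
        self.n_global_kernels = n_global_kernels
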