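"""scikit-learn style estimator facade over the classifier.

``ConformerVocalizationClassifier`` exposes the whole pipeline (feature
extraction, optional spectral gating, the encoder, margin-softmax
training) through the familiar ``fit`` / ``predict`` / ``predict_proba``
surface, so it composes with sklearn model selection. ``X`` is a sequence
of mono waveforms (1-D arrays or :class:`~pigvoc.audio.Waveform`), not a
rectangular matrix — clips may differ in duration and sampling rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .audio import Waveform
from .evaluation import SplitAssignment
from .model import AtfConformerNet, ModelConfig
from .synthetic import CLASSES, SAMPLE_RATE
from .training import (
    FeatureConfig, TrainConfig, extract_features, train, _prepared_inputs,
    _pad_batch, _batches,
)

__all__ = ["ConformerVocalizationClassifier"]


class ConformerVocalizationClassifier(ClassifierMixin, BaseEstimator):
    """Five-class vocalization classifier with a decoupled Conformer encoder.

    Parameters mirror the architecture and optimization settings; all are
    plain constructor arguments so ``get_params`` / ``set_params`` and grid
    search work unmodified.

    Examples
    --------
    >>> from pigvoc.synthetic import generate_dataset
    >>> m = generate_dataset(n_per_class=10, seed=0)
    >>> clf = ConformerVocalizationClassifier(model_dim=32, max_epochs=2)
    >>> clf.fit(m.waveforms(), m.records["label"])  # doctest: +ELLIPSIS
    ConformerVocalizationClassifier(...)
    """

    def __init__(
        self,
        model_dim: int = 128,
        n_blocks: int = 2,
        n_heads: int = 4,
        front_channels: int = 32,
        freq_kernel: int = 15,
        ffn_expansion: int = 4,
        dropout: float = 0.1,
        aam_scale: float = 30.0,
        aam_margin: float = 0.2,
        use_gating: bool = True,
        use_ta: bool = True,
        use_tfd: bool = True,
        conv_front_only: bool = False,
        learning_rate: float = 0.001,
        batch_size: int = 16,
        max_epochs: int = 100,
        early_stop_patience: int = 15,
        val_fraction: float = 0.1,
        seed: int = 42,
    ):
        self.model_dim = model_dim
        self.n_blocks = n_blocks
        self.n_heads = n_heads
        self.front_channels = front_channels
        self.freq_kernel = freq_kernel
        self.ffn_expansion = ffn_expansion
        self.dropout = dropout
        self.aam_scale = aam_scale
        self.aam_margin = aam_margin
        self.use_gating = use_gating
        self.use_ta = use_ta
        self.use_tfd = use_tfd
        self.conv_front_only = conv_front_only
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.val_fraction = val_fraction
        self.seed = seed

    # -- config assembly ------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            model_dim=self.model_dim, n_blocks=self.n_blocks,
            n_heads=self.n_heads, front_channels=self.front_channels,
            freq_kernel=self.freq_kernel, ffn_expansion=self.ffn_expansion,
            dropout=self.dropout, aam_scale=self.aam_scale,
            aam_margin=self.aam_margin, use_gating=self.use_gating,
            use_ta=self.use_ta, use_tfd=self.use_tfd,
            conv_front_only=self.conv_front_only,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            max_epochs=self.max_epochs, seed=self.seed,
            early_stop_patience=self.early_stop_patience,
        )

    @staticmethod
    def _as_waveforms(X) -> list[Waveform]:
        out = []
        for x in X:
            if isinstance(x, Waveform):
                out.append(x)
            else:
                out.append(Waveform(np.asarray(x, dtype=np.float64), SAMPLE_RATE))
        return out

    # -- estimator API --------------------------------------------------------
    def fit(self, X, y, groups=None):
        """Fit on waveform clips.

        ``groups`` (optional) holds group tokens; when given, the internal
        validation split is group-exclusive, otherwise it is a stratified
        random split.
        """
        waves = self._as_waveforms(X)
        y = np.asarray(y)
        if len(waves) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.array(CLASSES)
        self.feature_config_ = FeatureConfig()
        features = [extract_features(w, self.feature_config_) for w in waves]

        idx = np.arange(len(y))
        if groups is not None:
            groups = np.asarray(groups)
            uniq = np.unique(groups)
            rng = np.random.default_rng(self.seed)
            val_groups = set(
                rng.choice(uniq, max(1, int(round(self.val_fraction * len(uniq)))),
                           replace=False)
            )
            val_idx = idx[np.isin(groups, list(val_groups))]
            train_idx = idx[~np.isin(groups, list(val_groups))]
        else:
            train_idx, val_idx = train_test_split(
                idx, test_size=self.val_fraction, stratify=y,
                random_state=self.seed,
            )
        assignment = pd.Series("train", index=idx, dtype=object)
        assignment.iloc[val_idx] = "val"
        split = SplitAssignment(assignment, kind="holdout")

        tokens = groups if groups is not None else [f"clip{i}" for i in idx]
        manifest = _ArrayManifest(y, waves, tokens)
        self.run_record_ = train(
            self._model_config(), self._train_config(), split, manifest,
            features=features,
        )
        self.net_: AtfConformerNet = self.run_record_.net
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        waves = self._as_waveforms(X)
        features = [extract_features(w, self.feature_config_) for w in waves]
        xs, masks = _prepared_inputs(features, self.net_.cfg)
        probs = np.zeros((len(waves), len(self.classes_)))
        for chunk in _batches(np.arange(len(waves)), 32, None):
            x, m = _pad_batch(xs, masks, chunk)
            probs[chunk] = self.net_.predict_proba_batch(x, m)
        return probs

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


class _ArrayManifest:
    """Adapter giving plain (labels, waveforms) the manifest interface."""

    def __init__(self, labels, waves, tokens):
        self.records = pd.DataFrame(
            dict(sample_id=np.arange(len(labels)), label=labels,
                 pen_id=list(tokens), date="2025-01-01", session="morning",
                 pig_id=None, close_range=False, mode="routine")
        )
        self._waves = list(waves)

    def __len__(self):
        return len(self._waves)

    def waveform(self, i):
        return self._waves[i]
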