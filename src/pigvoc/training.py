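"""Training harness: shared feature pipeline, Adam optimization of the
margin-softmax objective, checkpoint selection on validation Macro-F1,
and the orchestration routines (grouped CV, LOSO, ablation suite).

Determinism contract: with a fixed (config, seed, manifest) every emitted
number is bit-identical on a single CPU thread — initialization, data
order and dropout all draw from generators derived from the seed.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .audio import (
    FrameMask, LogMelSpectrogram, Waveform, compute_log_mel,
    resample_normalize, trim_silence,
)
from .errors import ConfigurationError, DivergenceError
from .evaluation import (
    MetricsReport, SessionGeneralizationReport, SplitAssignment,
    compute_metrics, grouped_holdout_split, grouped_kfold, loso_by_session,
    oof_confusion, session_summary, verify_no_leakage,
)
from .model import AtfConformerNet, ModelConfig, prepare_input
from .synthetic import CLASSES, DatasetManifest

__all__ = [
    "FeatureConfig", "TrainConfig", "RunRecord", "Adam", "extract_features",
    "dataset_features", "train", "run_grouped_cv", "run_loso",
    "run_ablation_suite", "ABLATION_VARIANTS", "make_classifier",
    "evaluate_on_indices",
]


@dataclass
class FeatureConfig:
    """Shared input-construction settings (applied to every model alike)."""

    n_mels: int = 80
    frame_len_ms: float = 25.0
    hop_ms: float = 10.0
    fmin_hz: float = 0.0
    fmax_hz: float = 8000.0
    trim_threshold_db: float = 40.0
    target_rate: int = 16000


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 16
    max_epochs: int = 100
    seed: int = 42
    early_stop_patience: int = 15
    scheduler_factor: float = 0.5
    scheduler_patience: int = 5
    min_lr: float = 1e-6
    selection_metric: str = "val_macro_f1"

    def __post_init__(self):
        if self.learning_rate < 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigurationError("rates and counts must be positive")


@dataclass
class RunRecord:
    """Per-epoch log plus the retained best checkpoint."""

    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_macro_f1: float = -np.inf
    best_state: dict | None = None
    seed: int = 0
    started_at: float = 0.0
    finished_at: float = 0.0

    def val_curve(self) -> list[float]:
        return [e["val_macro_f1"] for e in self.epochs]


class Adam:
    """Adaptive-moment optimizer over a parameter list."""

    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


# ---------------------------------------------------------------------------
# Feature pipeline
# ---------------------------------------------------------------------------

def extract_features(
    w: Waveform, cfg: FeatureConfig | None = None
) -> tuple[LogMelSpectrogram, FrameMask]:
    """Resample + peak-normalize, log-Mel, trim silence -> (spec, mask)."""
    cfg = cfg or FeatureConfig()
    w = resample_normalize(w, cfg.target_rate)
    spec = compute_log_mel(
        w, n_mels=cfg.n_mels, frame_len_ms=cfg.frame_len_ms, hop_ms=cfg.hop_ms,
        fmin_hz=cfg.fmin_hz, fmax_hz=cfg.fmax_hz,
    )
    return trim_silence(spec, cfg.trim_threshold_db)


def dataset_features(
    manifest, cfg: FeatureConfig | None = None
) -> list[tuple[LogMelSpectrogram, FrameMask]]:
    """Features for every manifest record (regenerating waveforms)."""
    return [extract_features(manifest.waveform(i), cfg) for i in range(len(manifest))]


def _label_indices(labels) -> np.ndarray:
    lut = {c: i for i, c in enumerate(CLASSES)}
    return np.array([lut[l] for l in labels], dtype=int)


def _prepared_inputs(features, model_cfg: ModelConfig):
    """Gate + standardize every clip once (identical at train/inference)."""
    xs, masks = [], []
    for spec, mask in features:
        xs.append(prepare_input(spec, model_cfg))
        masks.append(mask.bits.astype(np.float32))
    return xs, masks


def _batches(indices: np.ndarray, batch_size: int, rng: np.random.Generator | None):
    idx = np.asarray(indices)
    if rng is not None:
        idx = idx.copy()
        rng.shuffle(idx)
    return [idx[i:i + batch_size] for i in range(0, len(idx), batch_size)]


def _pad_batch(xs, masks, batch):
    t_max = max(xs[i].shape[1] for i in batch)
    t_max += t_max % 2  # keep the 2x2 front-end pooling aligned
    f = xs[batch[0]].shape[0]
    x = np.zeros((len(batch), f, t_max), dtype=np.float32)
    m = np.zeros((len(batch), t_max), dtype=np.float32)
    for row, i in enumerate(batch):
        t = xs[i].shape[1]
        x[row, :, :t] = xs[i]
        m[row, :t] = masks[i]
    return x, m


def _predict_proba(net: AtfConformerNet, xs, masks, indices, batch_size: int = 32):
    probs = np.zeros((len(indices), net.cfg.n_classes))
    for chunk in _batches(np.arange(len(indices)), batch_size, None):
        batch = [indices[c] for c in chunk]
        x, m = _pad_batch(xs, masks, batch)
        probs[chunk] = net.predict_proba_batch(x, m)
    return probs


def evaluate_on_indices(
    net: AtfConformerNet, xs, masks, labels, indices, y_score: bool = True
) -> tuple[MetricsReport, np.ndarray, np.ndarray]:
    """Metrics + (y_pred, probabilities) for a subset of prepared clips."""
    probs = _predict_proba(net, xs, masks, np.asarray(indices))
    y_pred = np.array([CLASSES[i] for i in probs.argmax(axis=1)])
    y_true = np.asarray(labels)[np.asarray(indices)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = compute_metrics(y_true, y_pred, probs if y_score else None)
    return report, y_pred, probs


# ---------------------------------------------------------------------------
# The training loop
# ---------------------------------------------------------------------------

def train(
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    split: SplitAssignment,
    manifest: DatasetManifest,
    features=None,
    feature_cfg: FeatureConfig | None = None,
    net: AtfConformerNet | None = None,
) -> RunRecord:
    """Optimize the margin-softmax objective with checkpoint selection on
    validation Macro-F1, plateau LR reduction and early stopping.

    The split's leakage invariants are verified before the first epoch;
    a violating split aborts with ``LeakageError``.
    """
    if split.kind != "loso":
        verify_no_leakage(manifest, split)
    else:
        verify_no_leakage(manifest, split, check_parts=("train", "val"))
    if features is None:
        features = dataset_features(manifest, feature_cfg)
    labels = manifest.records["label"].to_numpy()
    y_idx = _label_indices(labels)
    xs, masks = _prepared_inputs(features, model_cfg)
    train_idx = split.indices("train")
    val_idx = split.indices("val")

    if net is None:
        net = AtfConformerNet(model_cfg, seed=train_cfg.seed)
    opt = Adam(net.parameters(), lr=train_cfg.learning_rate)
    order_rng = np.random.default_rng(
        np.random.SeedSequence(train_cfg.seed, spawn_key=(23,))
    )
    record = RunRecord(seed=train_cfg.seed, started_at=time.time())
    epochs_since_best = 0
    epochs_since_plateau = 0
    lr = train_cfg.learning_rate
    for epoch in range(train_cfg.max_epochs):
        net.train()
        losses = []
        for batch in _batches(train_idx, train_cfg.batch_size, order_rng):
            x, m = _pad_batch(xs, masks, batch)
            loss = net.loss(x, m, y_idx[batch])
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        report, _, _ = evaluate_on_indices(net, xs, masks, labels, val_idx,
                                           y_score=False)
        val_f1 = report.macro_f1
        record.epochs.append(
            dict(epoch=epoch, train_loss=float(np.mean(losses)),
                 val_macro_f1=val_f1, lr=lr)
        )
        if val_f1 > record.best_val_macro_f1:  # ties keep the earliest epoch
            record.best_val_macro_f1 = val_f1
            record.best_epoch = epoch
            record.best_state = net.state_dict()
            epochs_since_best = 0
            epochs_since_plateau = 0
        else:
            epochs_since_best += 1
            epochs_since_plateau += 1
        if epochs_since_plateau > train_cfg.scheduler_patience:
            lr = max(lr * train_cfg.scheduler_factor, train_cfg.min_lr)
            opt.lr = lr
            epochs_since_plateau = 0
        if epochs_since_best >= train_cfg.early_stop_patience:
            break
    if record.best_state is not None:
        net.load_state_dict(record.best_state)
    record.finished_at = time.time()
    record.net = net  # type: ignore[attr-defined]
    return record


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_grouped_cv(
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    manifest: DatasetManifest,
    k: int = 5,
    features=None,
    feature_cfg: FeatureConfig | None = None,
):
    """K-fold grouped cross-validation with out-of-fold confusion.

    Each fold's held-out groups form the validation set (also used for
    checkpoint selection, matching the development protocol); predictions
    are concatenated so every sample is scored exactly once by a model not
    trained on its group.
    """
    if features is None:
        features = dataset_features(manifest, feature_cfg)
    folds = grouped_kfold(manifest, k=k, seed=train_cfg.seed)
    labels = manifest.records["label"].to_numpy()
    reports: list[MetricsReport] = []
    fold_preds = []
    for f in range(k):
        assignment = pd.Series(
            np.where(folds.assignment.to_numpy() == f, "val", "train"),
            index=folds.assignment.index,
        )
        split = SplitAssignment(assignment, kind="holdout")
        rec = train(model_cfg, train_cfg, split, manifest, features=features)
        net = rec.net
        xs, masks = _prepared_inputs(features, model_cfg)
        val_idx = split.indices("val")
        report, y_pred, _ = evaluate_on_indices(net, xs, masks, labels, val_idx)
        reports.append(report)
        fold_preds.append((val_idx, labels[val_idx], y_pred))
    cm = oof_confusion(fold_preds, n_samples=len(manifest))
    return reports, cm


def run_loso(
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    manifest: DatasetManifest,
    features=None,
    feature_cfg: FeatureConfig | None = None,
) -> SessionGeneralizationReport:
    """Three trainings, each holding one recording session out as the test
    domain; reports per-session Macro-F1, mean +/- SD and the noon shift."""
    if features is None:
        features = dataset_features(manifest, feature_cfg)
    labels = manifest.records["label"].to_numpy()
    per_session = {}
    for session, split in loso_by_session(manifest, seed=train_cfg.seed):
        rec = train(model_cfg, train_cfg, split, manifest, features=features)
        xs, masks = _prepared_inputs(features, model_cfg)
        report, _, _ = evaluate_on_indices(
            rec.net, xs, masks, labels, split.indices("test")
        )
        per_session[session] = report.macro_f1
    return session_summary(per_session)


ABLATION_VARIANTS = (
    ("Full Model", {}),
    ("w/o Spectral Gating", {"use_gating": False}),
    ("w/o TA", {"use_ta": False}),
    ("w/o TFD-Conformer", {"use_tfd": False}),
    ("Conv-Front Only", {"conv_front_only": True}),
)


def run_ablation_suite(
    base_cfg: ModelConfig,
    train_cfg: TrainConfig,
    manifest: DatasetManifest,
    features=None,
    feature_cfg: FeatureConfig | None = None,
    variants=ABLATION_VARIANTS,
) -> pd.DataFrame:
    """Train/evaluate the full model and each single-removal variant on one
    identical grouped holdout split, shared features and seed."""
    if features is None:
        features = dataset_features(manifest, feature_cfg)
    split = grouped_holdout_split(manifest, seed=train_cfg.seed)
    labels = manifest.records["label"].to_numpy()
    rows = []
    for name, overrides in variants:
        cfg = replace(base_cfg, **overrides)
        rec = train(cfg, train_cfg, split, manifest, features=features)
        xs, masks = _prepared_inputs(features, cfg)
        report, _, _ = evaluate_on_indices(
            rec.net, xs, masks, labels, split.indices("test")
        )
        rows.append(
            dict(model=name, accuracy=report.accuracy,
                 macro_precision=report.macro_precision,
                 macro_recall=report.macro_recall, macro_f1=report.macro_f1,
                 n_parameters=rec.net.n_parameters())
        )
    return pd.DataFrame(rows)


def save_checkpoint(path, net: AtfConformerNet, train_cfg: TrainConfig | None = None):
    """Weights + model config + seed record in one .npz file."""
    import json

    from dataclasses import asdict

    meta = dict(model=asdict(net.cfg), seed=train_cfg.seed if train_cfg else None)
    meta["model"]["gating"] = asdict(net.cfg.gating)
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **net.state_dict())


def load_checkpoint(path) -> AtfConformerNet:
    import json

    from .audio import GatingConfig

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    mcfg = dict(meta["model"])
    mcfg["gating"] = GatingConfig(**mcfg["gating"])
    net = AtfConformerNet(ModelConfig(**mcfg), seed=meta.get("seed") or 0)
    net.load_state_dict(state)
    return net


def make_classifier(net: AtfConformerNet, feature_cfg: FeatureConfig | None = None):
    """Waveform -> predicted label through the shared feature pipeline."""
    fcfg = feature_cfg or FeatureConfig()

    def classify(w: Waveform) -> str:
        spec, mask = extract_features(w, fcfg)
        return net.forward(spec, mask).predicted_label

    return classify
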