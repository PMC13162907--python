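"""Five-class vocalization classifier with a time-frequency decoupled
Conformer encoder.

Pipeline (ablation switches in brackets):

    log-Mel -> [spectral gating] -> Conv2d/BN/ReLU/AvgPool front end
            -> [triplet attention] -> frame sequence (T' x D)
            -> n_blocks x encoder block -> masked attentive pooling
            -> cosine classification head (additive angular margin in training)

The encoder block is asymmetric by design: multi-head self-attention models
long-range structure along time (masked frames are excluded as attention
keys), while a short 1-D convolution acts locally along the feature axis of
each frame; the two branches are concatenated and fused by a feed-forward
network inside a residual + layer-norm wrapper. Setting ``use_tfd=False``
swaps in a standard symmetric Conformer block; ``conv_front_only=True``
short-circuits after the front end to global average pooling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import layers as L
from .audio import FrameMask, GatingConfig, LogMelSpectrogram, spectral_gate
from .autograd import Tensor, concat, no_grad
from .errors import ConfigurationError, InvalidInputError, NoValidFramesError
from .synthetic import CLASSES

__all__ = [
    "ModelConfig", "ClassPrediction", "AtfConformerNet", "aam_softmax_loss",
    "aam_softmax_loss_np", "masked_attentive_pooling_np", "downsample_mask",
    "prepare_input",
]

AAM_EPS = 1e-8  # pooling denominator constant
COS_CLIP = 1e-7


@dataclass
class ModelConfig:
    """Architecture plus ablation switches (one per reported variant)."""

    n_classes: int = 5
    n_mels: int = 80
    front_channels: int = 32
    model_dim: int = 128
    n_heads: int = 4
    n_blocks: int = 2
    freq_kernel: int = 15
    ffn_expansion: int = 4
    dropout: float = 0.1
    aam_scale: float = 30.0
    aam_margin: float = 0.2
    use_gating: bool = True
    use_ta: bool = True
    use_tfd: bool = True
    conv_front_only: bool = False
    use_positional_encoding: bool = True
    gating: GatingConfig = field(default_factory=GatingConfig)

    def __post_init__(self):
        if self.model_dim % self.n_heads != 0:
            raise ConfigurationError("model_dim must be divisible by n_heads")
        if self.freq_kernel % 2 != 1:
            raise ConfigurationError("freq_kernel must be odd")
        if not 0 <= self.aam_margin < math.pi / 2:
            raise ConfigurationError("aam_margin must lie in [0, pi/2)")
        if self.aam_scale <= 0:
            raise ConfigurationError("aam_scale must be positive")


@dataclass
class ClassPrediction:
    logits: np.ndarray
    probabilities: np.ndarray
    predicted_label: str

    def __post_init__(self):
        if abs(self.probabilities.sum() - 1.0) > 1e-6:
            raise InvalidInputError("probabilities must sum to 1")


# ---------------------------------------------------------------------------
# Input preparation
# ---------------------------------------------------------------------------

def prepare_input(spec: LogMelSpectrogram, cfg: ModelConfig) -> np.ndarray:
    """Spectral gating (if enabled) followed by per-clip standardisation."""
    if cfg.use_gating:
        spec = spectral_gate(spec, cfg.gating)
    v = spec.values
    return ((v - v.mean()) / (v.std() + 1e-6)).astype(np.float32)


def downsample_mask(bits: np.ndarray, factor: int = 2) -> np.ndarray:
    """Align an input-resolution frame mask with the encoder's frame rate.

    A pooled frame is valid when any of its source frames is valid.
    """
    t = len(bits) // factor * factor
    return bits[:t].reshape(-1, factor).max(axis=1)


# ---------------------------------------------------------------------------
# Triplet attention
# ---------------------------------------------------------------------------

def _zpool(x: Tensor) -> Tensor:
    """Concatenate max- and mean-pooling over axis 1 -> 2 channels."""
    return concat([x.max(axis=1, keepdims=True), x.mean(axis=1, keepdims=True)], axis=1)


class TripletAttention(L.Module):
    """Sigmoid gates over three rotated axis-pair views of (B, C, F, T).

    Each branch compresses the remaining axis with a 2-channel Z-pool
    (max + mean), passes a 7x7 convolution and a sigmoid to get a gate in
    (0, 1), multiplies elementwise, and rotates back; the output is the
    arithmetic mean of the three gated branches. ``gates`` overrides the
    computed gates (diagnostic hook used to verify the fusion rule).
    """

    def __init__(self, rng: np.random.Generator, kernel_size: int = 7):
        super().__init__()
        self.conv_tf = L.Conv2d(2, 1, kernel_size, rng)  # compress C
        self.conv_ct = L.Conv2d(2, 1, kernel_size, rng)  # compress F
        self.conv_cf = L.Conv2d(2, 1, kernel_size, rng)  # compress T

    def _branch(self, x: Tensor, conv: L.Conv2d, gate: np.ndarray | None) -> Tensor:
        if gate is not None:
            return x * Tensor(gate)
        a = conv(_zpool(x)).sigmoid()  # (B, 1, d1, d2)
        return x * a

    def forward(self, x: Tensor, gates=None) -> Tensor:
        g_ct, g_cf, g_tf = gates if gates is not None else (None, None, None)
        # time-frequency view: compress channels (no rotation needed)
        h_tf = self._branch(x, self.conv_tf, g_tf)
        # channel-time view: rotate F into the pooled position
        x_ct = x.transpose(0, 2, 1, 3)  # (B, F, C, T)
        h_ct = self._branch(x_ct, self.conv_ct, g_ct).transpose(0, 2, 1, 3)
        # channel-frequency view: rotate T into the pooled position
        x_cf = x.transpose(0, 3, 2, 1)  # (B, T, F, C) -> pool over T
        h_cf = self._branch(x_cf, self.conv_cf, g_cf).transpose(0, 3, 2, 1)
        return (h_ct + h_cf + h_tf) * (1.0 / 3.0)


# ---------------------------------------------------------------------------
# Encoder blocks
# ---------------------------------------------------------------------------

class FeedForward(L.Module):
    def __init__(self, d_in: int, d_out: int, expansion: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.lin1 = L.Linear(d_in, expansion * d_out, rng)
        self.lin2 = L.Linear(expansion * d_out, d_out, rng)
        self.drop = L.Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.drop(self.lin2(self.drop(self.lin1(x).silu())))


class TfdConformerBlock(L.Module):
    """Time-global attention + frequency-local convolution, FFN-fused."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.model_dim
        self.ln_in = L.LayerNorm(d)
        self.mhsa = L.MultiHeadSelfAttention(d, cfg.n_heads, rng)
        k = cfg.freq_kernel
        self.freq_kernel = L.Parameter(rng.uniform(-1, 1, k) / math.sqrt(k))
        self.freq_bias = L.Parameter(np.zeros(d))
        self.ffn = FeedForward(2 * d, d, cfg.ffn_expansion, cfg.dropout, rng)
        self.ln_out = L.LayerNorm(d)

    def forward(self, x: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        if key_mask is not None and not np.asarray(key_mask).any():
            raise NoValidFramesError("all frames masked")
        h = self.ln_in(x)
        h_t = self.mhsa(h, key_mask)  # temporal branch, global
        h_f = L.conv_along_features(h, self.freq_kernel, self.freq_bias)  # local
        fused = self.ffn(concat([h_t, h_f], axis=-1))
        return self.ln_out(x + fused)


class StandardConformerBlock(L.Module):
    """Symmetric Conformer block (the "w/o TFD" ablation backbone):
    half-step FFN, MHSA, temporal depthwise conv module, half-step FFN."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.model_dim
        self.ffn1 = FeedForward(d, d, cfg.ffn_expansion, cfg.dropout, rng)
        self.ln1 = L.LayerNorm(d)
        self.ln2 = L.LayerNorm(d)
        self.mhsa = L.MultiHeadSelfAttention(d, cfg.n_heads, rng)
        self.ln3 = L.LayerNorm(d)
        self.pw1 = L.Linear(d, 2 * d, rng)
        self.dw_kernel = L.Parameter(
            rng.uniform(-1, 1, (d, cfg.freq_kernel)) / math.sqrt(cfg.freq_kernel)
        )
        self.pw2 = L.Linear(d, d, rng)
        self.ffn2 = FeedForward(d, d, cfg.ffn_expansion, cfg.dropout, rng)
        self.ln4 = L.LayerNorm(d)
        self.ln_final = L.LayerNorm(d)

    def forward(self, x: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        if key_mask is not None and not np.asarray(key_mask).any():
            raise NoValidFramesError("all frames masked")
        x = x + self.ffn1(self.ln1(x)) * 0.5
        x = x + self.mhsa(self.ln2(x), key_mask)
        h = self.pw1(self.ln3(x))
        d = x.shape[-1]
        a, b = h[:, :, :d], h[:, :, d:]
        h = a * b.sigmoid()  # GLU
        h = L.depthwise_conv_time(h, self.dw_kernel).silu()
        x = x + self.pw2(h)
        x = x + self.ffn2(self.ln4(x)) * 0.5
        return self.ln_final(x)


class MaskedAttentivePooling(L.Module):
    """Attention-weighted mean over valid frames.

    alpha = softmax(W_p h_t) computed only over frames with m_t = 1 (masked
    frames receive -inf logits), then z = sum(m a h) / (sum(m a) + eps).
    With the renormalised alpha the content of masked frames cannot affect
    z at all.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.w_p = L.Linear(dim, 1, rng, bias=False)

    def forward(self, h: Tensor, mask: np.ndarray) -> Tensor:
        mask = np.asarray(mask, dtype=h.data.dtype)
        if mask.ndim == 1:
            mask = mask[None, :]
        if not (mask.sum(axis=1) > 0).all():
            raise NoValidFramesError("a sample has no valid frames")
        scores = self.w_p(h)[:, :, 0]  # (B, T)
        scores = scores + Tensor(np.where(mask > 0, 0.0, -1e9).astype(mask.dtype))
        alpha = scores.softmax(axis=-1)  # zero on masked frames
        m = Tensor(mask)
        num = (h * (alpha * m).reshape(alpha.shape[0], alpha.shape[1], 1)).sum(axis=1)
        den = (alpha * m).sum(axis=1, keepdims=True) + AAM_EPS
        return num / den


# ---------------------------------------------------------------------------
# AAM-Softmax
# ---------------------------------------------------------------------------

def _normalize_rows(x: Tensor) -> Tensor:
    norm = ((x * x).sum(axis=-1, keepdims=True) + 1e-12).sqrt()
    return x / norm


def aam_softmax_loss(emb: Tensor, labels: np.ndarray, weights: Tensor,
                     s: float, m: float) -> Tensor:
    """Additive angular margin cross-entropy (differentiable).

    cos(theta_j) from L2-normalised embeddings and class weights; the true
    class angle gets the margin m, with theta_y + m clamped to [0, pi].
    """
    emb_norms = np.sqrt((emb.data ** 2).sum(axis=-1))
    if np.any(emb_norms <= 0) or np.any(np.sqrt((weights.data ** 2).sum(-1)) <= 0):
        raise InvalidInputError("zero-norm embedding or class weight")
    cos = _normalize_rows(emb) @ _normalize_rows(weights).transpose(1, 0)  # (B, C)
    onehot = np.zeros(cos.shape, dtype=cos.data.dtype)
    onehot[np.arange(len(labels)), labels] = 1.0
    oh = Tensor(onehot)
    cos_y = (cos * oh).sum(axis=-1, keepdims=True)
    clip_eps = COS_CLIP if cos.data.dtype == np.float32 else 1e-12
    theta = cos_y.clip(-1.0 + clip_eps, 1.0 - clip_eps).arccos()
    cos_margin = (theta + m).clip(0.0, math.pi).cos()
    logits = (cos + oh * (cos_margin - cos_y)) * s
    logp = logits - _logsumexp(logits)
    nll = -(logp * oh).sum(axis=-1)
    return nll.mean()


def _logsumexp(x: Tensor) -> Tensor:
    shift = Tensor(x.data.max(axis=-1, keepdims=True))
    return ((x - shift).exp().sum(axis=-1, keepdims=True)).log() + shift


def aam_softmax_loss_np(emb: np.ndarray, label: int | np.ndarray,
                        weights: np.ndarray, s: float, m: float) -> float:
    """Convenience evaluation on plain arrays (single sample or batch)."""
    emb = np.atleast_2d(np.asarray(emb, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(label, dtype=int))
    with no_grad():
        out = aam_softmax_loss(Tensor(emb), labels, Tensor(weights), s, m)
    return float(out.data)


def masked_attentive_pooling_np(seq: np.ndarray, mask: np.ndarray,
                                w_p: np.ndarray) -> np.ndarray:
    """Functional masked pooling on arrays (T x D sequence -> D vector)."""
    seq = np.asarray(seq, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if mask.sum() == 0:
        raise NoValidFramesError("all frames masked")
    scores = seq @ np.asarray(w_p, dtype=np.float64).reshape(-1)
    scores = np.where(mask > 0, scores, -np.inf)
    scores = scores - scores.max()
    e = np.exp(scores)
    alpha = e / e.sum()
    num = (mask[:, None] * alpha[:, None] * seq).sum(axis=0)
    den = (mask * alpha).sum() + AAM_EPS
    return num / den


# ---------------------------------------------------------------------------
# The full network
# ---------------------------------------------------------------------------

class AtfConformerNet(L.Module):
    """The complete classifier network; submodules follow the config flags."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11,)))
        c, d = cfg.front_channels, cfg.model_dim
        self.front_conv = L.Conv2d(1, c, 3, rng)
        self.front_bn = L.BatchNorm2d(c)
        f_prime = cfg.n_mels // 2
        if cfg.conv_front_only:
            self.gap_proj = L.Linear(c, d, rng)
        else:
            if cfg.use_ta:
                self.ta = TripletAttention(rng)
            self.seq_proj = L.Linear(c * f_prime, d, rng)
            block_cls = TfdConformerBlock if cfg.use_tfd else StandardConformerBlock
            for i in range(cfg.n_blocks):
                setattr(self, f"block{i}", block_cls(cfg, rng))
            self.pool = MaskedAttentivePooling(d, rng)
        self.class_weights = L.Parameter(
            rng.standard_normal((cfg.n_classes, d)) / math.sqrt(d)
        )

    # -- stages ---------------------------------------------------------------
    def conv_front_end(self, x: Tensor) -> Tensor:
        """(B, F, T) -> (B, C', F/2, T/2) via Conv-BN-ReLU-AvgPool."""
        if x.shape[-1] < 2:
            raise InvalidInputError("need at least 2 frames")
        h = self.front_conv(x.reshape(x.shape[0], 1, x.shape[1], x.shape[2]))
        h = self.front_bn(h).relu()
        return L.avg_pool_2x2(h)

    def to_frame_sequence(self, feat: Tensor) -> Tensor:
        """(B, C', F', T') -> (B, T', D): flatten each time step, project."""
        b, c, f, t = feat.shape
        h = feat.transpose(0, 3, 1, 2).reshape(b, t, c * f)
        return self.seq_proj(h)

    def blocks(self):
        return [getattr(self, f"block{i}") for i in range(self.cfg.n_blocks)]

    def embed(self, x: Tensor, mask: np.ndarray) -> Tensor:
        """Prepared input batch (B, F, T) + input-resolution mask (B, T) ->
        utterance embeddings (B, D)."""
        feat = self.conv_front_end(x)
        if self.cfg.conv_front_only:
            pooled = feat.mean(axis=(2, 3))  # global average pool
            return self.gap_proj(pooled)
        if self.cfg.use_ta:
            feat = self.ta(feat)
        seq = self.to_frame_sequence(feat)
        enc_mask = np.stack([downsample_mask(m) for m in np.atleast_2d(mask)])
        enc_mask = enc_mask[:, : seq.shape[1]]
        if self.cfg.use_positional_encoding:
            seq = seq + Tensor(L.sinusoidal_positions(seq.shape[1], seq.shape[2]))
        for block in self.blocks():
            seq = block(seq, enc_mask)
        return self.pool(seq, enc_mask)

    def cosine_logits(self, emb: Tensor) -> Tensor:
        return _normalize_rows(emb) @ _normalize_rows(self.class_weights).transpose(1, 0)

    # -- inference ------------------------------------------------------------
    def forward(self, spec: LogMelSpectrogram, mask: FrameMask | np.ndarray) -> ClassPrediction:
        """Single-clip inference: gate (if enabled), standardise, classify."""
        bits = mask.bits if isinstance(mask, FrameMask) else np.asarray(mask)
        x = prepare_input(spec, self.cfg)
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                emb = self.embed(Tensor(x[None]), bits[None])
                logits = self.cosine_logits(emb) * self.cfg.aam_scale
                probs = logits.softmax(axis=-1).data[0]
        finally:
            self.train(was_training)
        return ClassPrediction(
            logits=logits.data[0], probabilities=probs,
            predicted_label=CLASSES[int(np.argmax(probs))],
        )

    def predict_proba_batch(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Batched inference on prepared inputs (B, F, T) + masks (B, T)."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                emb = self.embed(Tensor(x), mask)
                logits = self.cosine_logits(emb) * self.cfg.aam_scale
                return logits.softmax(axis=-1).data
        finally:
            self.train(was_training)

    def loss(self, x: np.ndarray, mask: np.ndarray, labels: np.ndarray) -> Tensor:
        emb = self.embed(Tensor(x), mask)
        return aam_softmax_loss(
            emb, labels, self.class_weights, self.cfg.aam_scale, self.cfg.aam_margin
        )
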