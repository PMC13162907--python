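"""Audio ingestion and the shared input-construction pipeline.

All clips go through the same steps before modelling: resample to 16 kHz,
peak-normalize, extract an 80-band log-Mel spectrogram (25 ms frames,
10 ms hop, 0-8 kHz), trim leading/trailing silent frames, and optionally
apply adaptive spectral gating that softly attenuates time-frequency cells
near a per-band noise floor. Spectrogram values are on a dB scale
(``10*log10(power + eps)``); all thresholds and offsets below are in dB.

The framing convention is explicit and analytically checkable: no center
padding, so a clip of N samples yields ``1 + floor((N - win) / hop)``
frames with win = 400 and hop = 160 samples at 16 kHz.
"""

from __future__ import annotations

import wave
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, EmptySegmentError, InvalidInputError, ParseError

__all__ = [
    "Waveform", "LogMelSpectrogram", "FrameMask", "GatingConfig",
    "SegmentAnnotation", "read_wav", "write_wav", "resample_normalize",
    "compute_log_mel", "trim_silence", "spectral_gate",
    "read_textgrid_segments", "write_textgrid", "estimate_dominant_band",
    "mel_frequencies", "mel_filterbank", "frame_energy_db",
]

LOG_FLOOR_POWER = 1e-10  # additive floor on mel power before the log
DB_FLOOR = 10.0 * np.log10(LOG_FLOOR_POWER)  # value of an all-zero frame


@dataclass
class Waveform:
    """Mono audio; samples are dimensionless amplitudes."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise InvalidInputError("waveform must be mono (1-D)")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class LogMelSpectrogram:
    """F x T matrix of log mel energies (dB scale)."""

    values: np.ndarray
    n_mels: int = 80
    frame_len_ms: float = 25.0
    hop_ms: float = 10.0
    fmin_hz: float = 0.0
    fmax_hz: float = 8000.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.n_mels:
            raise InvalidInputError(
                f"expected {self.n_mels} x T matrix, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("non-finite values in spectrogram")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class FrameMask:
    """Per-frame validity bits; 1 = valid, 0 = suppressed."""

    bits: np.ndarray

    def __post_init__(self):
        self.bits = np.asarray(self.bits)
        if not np.isin(self.bits, (0, 1)).all():
            raise InvalidInputError("mask bits must be 0/1")
        self.bits = self.bits.astype(np.int8)

    def __len__(self) -> int:
        return len(self.bits)


@dataclass
class GatingConfig:
    """Adaptive spectral gating in the log-Mel domain.

    Per mel band the noise floor is a percentile of that band's frame
    values; a sigmoid of the dB distance above (floor + offset) gives a
    soft gain in [min_gain, 1] that is applied to the linear amplitude
    (i.e. ``20*log10(gain)`` dB of attenuation).
    """

    noise_floor_percentile: float = 20.0
    threshold_offset_db: float = 3.0
    mask_slope: float = 1.0  # sigmoid steepness per dB
    min_gain: float = 0.1

    def __post_init__(self):
        if not 0 < self.noise_floor_percentile < 100:
            raise ConfigurationError("percentile must be in (0, 100)")
        if not 0 <= self.min_gain <= 1:
            raise ConfigurationError("min_gain must be in [0, 1]")


@dataclass
class SegmentAnnotation:
    label: str
    start_s: float
    end_s: float
    tier: str = ""

    def __post_init__(self):
        if not 0 <= self.start_s < self.end_s:
            raise InvalidInputError("need 0 <= start < end")


# ---------------------------------------------------------------------------
# WAV I/O (RIFF PCM 16-bit mono)
# ---------------------------------------------------------------------------

def read_wav(path: str | Path) -> Waveform:
    with wave.open(str(path), "rb") as f:
        if f.getnchannels() != 1 or f.getsampwidth() != 2:
            raise ParseError("expected 16-bit mono PCM WAV")
        rate = f.getframerate()
        raw = f.readframes(f.getnframes())
    samples = np.frombuffer(raw, dtype="<i2").astype(np.float64) / 32768.0
    return Waveform(samples, rate)


def write_wav(path: str | Path, w: Waveform) -> None:
    ints = np.clip(np.round(w.samples * 32768.0), -32768, 32767).astype("<i2")
    with wave.open(str(path), "wb") as f:
        f.setnchannels(1)
        f.setsampwidth(2)
        f.setframerate(w.sample_rate)
        f.writeframes(ints.tobytes())


# ---------------------------------------------------------------------------
# Resampling and normalization
# ---------------------------------------------------------------------------

def resample_normalize(w: Waveform, target_rate: int = 16000) -> Waveform:
    """Resample to ``target_rate`` and peak-normalize to max |sample| = 1.

    An all-zero input stays all-zero (no division blow-up).
    """
    if len(w.samples) == 0:
        raise InvalidInputError("empty waveform")
    if w.sample_rate != target_rate:
        from math import gcd

        g = gcd(target_rate, w.sample_rate)
        samples = sps.resample_poly(w.samples, target_rate // g, w.sample_rate // g)
    else:
        samples = w.samples.copy()
    peak = np.max(np.abs(samples))
    if peak > 0:
        samples = samples / peak
    return Waveform(samples, target_rate)


# ---------------------------------------------------------------------------
# Mel filterbank and log-Mel extraction
# ---------------------------------------------------------------------------

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_frequencies(n_mels: int, fmin_hz: float, fmax_hz: float) -> np.ndarray:
    """n_mels + 2 mel-spaced edge frequencies in Hz (HTK mel scale)."""
    mels = np.linspace(_hz_to_mel(fmin_hz), _hz_to_mel(fmax_hz), n_mels + 2)
    return _mel_to_hz(mels)


def mel_filterbank(n_mels: int, n_fft: int, sample_rate: int,
                   fmin_hz: float, fmax_hz: float) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft // 2 + 1)."""
    edges = mel_frequencies(n_mels, fmin_hz, fmax_hz)
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    fb = np.zeros((n_mels, len(fft_freqs)))
    for i in range(n_mels):
        lo, ctr, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        # unit-area (Slaney-style) normalization keeps a flat spectrum flat
        # across mel bands of growing bandwidth
        fb[i] = np.maximum(0.0, np.minimum(up, down)) * (2.0 / (hi - lo))
    return fb


def compute_log_mel(
    w: Waveform,
    n_mels: int = 80,
    frame_len_ms: float = 25.0,
    hop_ms: float = 10.0,
    fmin_hz: float = 0.0,
    fmax_hz: float = 8000.0,
) -> LogMelSpectrogram:
    """80-band log-Mel spectrogram with explicit (non-centered) framing.

    T = 1 + floor((N - win) / hop); values are 10*log10(mel power + 1e-10).
    """
    if w.sample_rate != 16000:
        raise InvalidInputError("expected a 16 kHz waveform; resample first")
    win = int(round(frame_len_ms * w.sample_rate / 1000.0))
    hop = int(round(hop_ms * w.sample_rate / 1000.0))
    n = len(w.samples)
    if n < win:
        raise InvalidInputError(f"waveform shorter than one window ({n} < {win})")
    n_frames = 1 + (n - win) // hop
    frames = np.lib.stride_tricks.sliding_window_view(w.samples, win)[::hop][:n_frames]
    window = sps.get_window("hann", win, fftbins=True)
    n_fft = 1 << (win - 1).bit_length()  # next power of two >= win
    spectrum = np.fft.rfft(frames * window, n=n_fft, axis=1)
    power = np.abs(spectrum) ** 2
    fb = mel_filterbank(n_mels, n_fft, w.sample_rate, fmin_hz, fmax_hz)
    mel_power = power @ fb.T  # (T, n_mels)
    values = 10.0 * np.log10(mel_power + LOG_FLOOR_POWER)
    return LogMelSpectrogram(
        values.T, n_mels=n_mels, frame_len_ms=frame_len_ms, hop_ms=hop_ms,
        fmin_hz=fmin_hz, fmax_hz=fmax_hz,
    )


def frame_energy_db(spec: LogMelSpectrogram) -> np.ndarray:
    """Total per-frame energy in dB (sum of linear mel power over bands)."""
    linear = 10.0 ** (spec.values / 10.0)
    return 10.0 * np.log10(linear.sum(axis=0) + LOG_FLOOR_POWER)


def trim_silence(
    spec: LogMelSpectrogram, energy_threshold_db: float = 40.0
) -> tuple[LogMelSpectrogram, FrameMask]:
    """Remove leading/trailing frames more than ``energy_threshold_db`` below
    the loudest frame; interior frames are never removed.

    Returns the trimmed spectrogram and a mask flagging residual low-energy
    interior frames (0 = below threshold) for masked pooling.
    """
    energy = frame_energy_db(spec)
    thresh = energy.max() - energy_threshold_db
    active = energy >= thresh
    if not active.any():
        raise EmptySegmentError("all frames below the silence threshold")
    first = int(np.argmax(active))
    last = len(active) - int(np.argmax(active[::-1]))
    trimmed = LogMelSpectrogram(
        spec.values[:, first:last], n_mels=spec.n_mels,
        frame_len_ms=spec.frame_len_ms, hop_ms=spec.hop_ms,
        fmin_hz=spec.fmin_hz, fmax_hz=spec.fmax_hz,
    )
    mask = FrameMask(active[first:last].astype(np.int8))
    return trimmed, mask


def spectral_gate(spec: LogMelSpectrogram, cfg: GatingConfig | None = None) -> LogMelSpectrogram:
    """Adaptive noise suppression in the log-Mel domain.

    Per mel band, the noise floor is ``cfg.noise_floor_percentile`` of that
    band's frame values; cells get a soft gain
    ``g = min_gain + (1 - min_gain) * sigmoid((v - floor - offset) * slope)``
    applied to the linear amplitude, i.e. the output is
    ``v + 20*log10(g)`` dB. With ``min_gain = 1`` the operation is the
    identity. Deterministic, identical at train and inference time.
    """
    cfg = cfg or GatingConfig()
    if spec.n_frames < 2:
        raise InvalidInputError("need at least 2 frames to estimate a noise floor")
    gain = gating_gain(spec, cfg)
    values = spec.values + 20.0 * np.log10(gain)
    return LogMelSpectrogram(
        values, n_mels=spec.n_mels, frame_len_ms=spec.frame_len_ms,
        hop_ms=spec.hop_ms, fmin_hz=spec.fmin_hz, fmax_hz=spec.fmax_hz,
    )


def gating_gain(spec: LogMelSpectrogram, cfg: GatingConfig) -> np.ndarray:
    """The soft mask g in [min_gain, 1] used by :func:`spectral_gate`."""
    floor = np.percentile(spec.values, cfg.noise_floor_percentile, axis=1, keepdims=True)
    x = (spec.values - floor - cfg.threshold_offset_db) * cfg.mask_slope
    sig = 1.0 / (1.0 + np.exp(-x))
    return cfg.min_gain + (1.0 - cfg.min_gain) * sig


# ---------------------------------------------------------------------------
# Praat TextGrid (long format) interval annotations
# ---------------------------------------------------------------------------

def read_textgrid_segments(path: str | Path, tier_name: str) -> list[SegmentAnnotation]:
    """Read non-empty labelled intervals from a long-format TextGrid tier."""
    tiers = _parse_textgrid(Path(path).read_text(encoding="utf-8"))
    if tier_name not in tiers:
        raise ConfigurationError(
            f"tier {tier_name!r} not found; available: {sorted(tiers)}"
        )
    out = []
    for xmin, xmax, text in tiers[tier_name]:
        if text.strip():
            out.append(SegmentAnnotation(text.strip(), xmin, xmax, tier=tier_name))
    return out


def _parse_textgrid(text: str) -> dict[str, list[tuple[float, float, str]]]:
    lines = [ln.strip() for ln in text.splitlines()]
    if not any("TextGrid" in ln for ln in lines[:5]):
        raise ParseError("not a Praat TextGrid file")

    def value_of(line: str) -> str:
        return line.split("=", 1)[1].strip()

    tiers: dict[str, list[tuple[float, float, str]]] = {}
    i = 0
    current: str | None = None
    is_interval = False
    pending: dict[str, float | str] = {}
    try:
        while i < len(lines):
            ln = lines[i]
            if ln.startswith("class"):
                is_interval = "IntervalTier" in ln
            elif ln.startswith("name") and "=" in ln:
                current = value_of(ln).strip('"')
                if is_interval:
                    tiers[current] = []
            elif is_interval and current is not None:
                if ln.startswith("xmin") and "intervals" in lines[i - 1]:
                    pending = {"xmin": float(value_of(ln))}
                elif ln.startswith("xmax") and "xmin" in pending and "xmax" not in pending:
                    pending["xmax"] = float(value_of(ln))
                elif ln.startswith("text") and "xmax" in pending:
                    label = value_of(ln).strip('"')
                    tiers[current].append(
                        (float(pending["xmin"]), float(pending["xmax"]), label)
                    )
                    pending = {}
            i += 1
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed TextGrid: {exc}") from exc
    return tiers


def write_textgrid(
    path: str | Path,
    segments: list[SegmentAnnotation],
    tier_name: str = "events",
    total_duration_s: float | None = None,
) -> None:
    """Write a long-format TextGrid with one interval tier.

    Gaps between annotated segments are written as empty-text intervals.
    """
    segs = sorted(segments, key=lambda s: s.start_s)
    end = total_duration_s if total_duration_s is not None else (
        segs[-1].end_s if segs else 1.0
    )
    intervals: list[tuple[float, float, str]] = []
    cursor = 0.0
    for s in segs:
        if s.start_s > cursor:
            intervals.append((cursor, s.start_s, ""))
        intervals.append((s.start_s, s.end_s, s.label))
        cursor = s.end_s
    if cursor < end:
        intervals.append((cursor, end, ""))
    if not intervals:
        intervals = [(0.0, end, "")]
    out = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {end}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        f'        name = "{tier_name}"',
        "        xmin = 0",
        f"        xmax = {end}",
        f"        intervals: size = {len(intervals)}",
    ]
    for j, (a, b, lab) in enumerate(intervals, 1):
        out += [
            f"        intervals [{j}]:",
            f"            xmin = {a}",
            f"            xmax = {b}",
            f'            text = "{lab}"',
        ]
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Dominant-band estimation (class-wise averaged spectrograms)
# ---------------------------------------------------------------------------

def estimate_dominant_band(
    specs: list[LogMelSpectrogram], fraction_of_peak: float = 0.25
) -> tuple[float, float]:
    """Dominant energy band of a set of spectrograms, in Hz.

    Spectrograms are averaged over time and samples (in linear power); the
    returned interval spans the contiguous range from the first to the last
    mel band whose mean energy is at least ``fraction_of_peak`` of the peak,
    mapped to Hz via the mel band edges.
    """
    if not specs:
        raise InvalidInputError("empty spectrogram list")
    n_mels = specs[0].n_mels
    if any(s.n_mels != n_mels for s in specs):
        raise InvalidInputError("all spectrograms must share the mel resolution")
    means = [np.mean(10.0 ** (s.values / 10.0), axis=1) for s in specs]
    profile = np.mean(means, axis=0)
    above = profile >= fraction_of_peak * profile.max()
    lo_bin = int(np.argmax(above))
    hi_bin = n_mels - 1 - int(np.argmax(above[::-1]))
    edges = mel_frequencies(n_mels, specs[0].fmin_hz, specs[0].fmax_hz)
    # band i covers [edges[i], edges[i + 2]]
    return float(edges[lo_bin]), float(edges[hi_bin + 2])
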