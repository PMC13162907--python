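"""Single YAML experiment configuration.

Sections map field-for-field onto the dataclasses:
``[features]`` -> FeatureConfig, ``[model]`` -> ModelConfig,
``[train]`` -> TrainConfig, ``[synth]`` -> SynthConfig,
``[eval]`` -> free-form evaluation options (k, snr_bins, ...).
Unknown keys raise, so typos fail fast.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .model import ModelConfig
from .synthetic import SynthConfig
from .training import FeatureConfig, TrainConfig

__all__ = ["ExperimentConfig", "load_config"]

_SECTIONS = {
    "features": FeatureConfig,
    "model": ModelConfig,
    "train": TrainConfig,
    "synth": SynthConfig,
}


class ExperimentConfig:
    def __init__(self, features=None, model=None, train=None, synth=None,
                 eval_options=None):
        self.features = features or FeatureConfig()
        self.model = model or ModelConfig()
        self.train = train or TrainConfig()
        self.synth = synth or SynthConfig()
        self.eval_options = eval_options or {}


def _build(cls, section: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ConfigurationError(f"unknown keys in [{name}]: {sorted(unknown)}")
    return cls(**section)


def load_config(path: str | Path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"eval"}
    if unknown:
        raise ConfigurationError(f"unknown sections: {sorted(unknown)}")
    kwargs = {
        name: _build(cls, raw.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    return ExperimentConfig(eval_options=raw.get("eval", {}) or {}, **kwargs)
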