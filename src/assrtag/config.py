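"""Structured run configuration: schema-validated YAML for the pipeline.

Unknown keys are rejected outright rather than ignored, so typos in a
config file fail loudly before any computation starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .decoder import DecoderConfig
from .signalgen import NeuralSimConfig, StimulusConfig


class ConfigError(ValueError):
    """Invalid or unknown run-configuration contents."""


def _build(cls, section: dict[str, Any], name: str):
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown keys in '{name}' section: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{name}' section: {exc}") from exc


@dataclass(frozen=True)
class StatsOptions:
    n_shuffles: int = 10_000
    alpha: float = 0.05


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs, under a single master seed."""

    seed: int = 0
    n_subjects: int = 1
    tag_freqs: tuple[float, float] = (39.0, 43.0)
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    simulation: NeuralSimConfig = field(default_factory=NeuralSimConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    stats: StatsOptions = field(default_factory=StatsOptions)
    timecourse_enabled: bool = False
    timecourse_win_len: float = 1.0
    timecourse_step: float = 0.05
    output_dir: str = "assrtag_results"

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw or {})
        sections = {
            "stimulus": StimulusConfig,
            "simulation": NeuralSimConfig,
            "decoder": DecoderConfig,
            "stats": StatsOptions,
        }
        kwargs: dict[str, Any] = {}
        for key, klass in sections.items():
            if key in raw:
                kwargs[key] = _build(klass, raw.pop(key) or {}, key)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        for k, v in raw.items():
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw is not None and not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(raw or {})
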