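"""Pipeline configuration: one YAML document with per-stage sections.

Example::

    sim:
      n_subjects: 17
      n_repetitions: 3
      separation: 1.0
    features:
      wavelet_level: 10
    train:
      hidden_nodes: 25
      hidden_layers: 1
    hmm:
      self_prob: 0.995
      emission_correct: 0.9
      start_at_first: true
    eval:
      k: 5
      seed: 0

Unknown keys anywhere are rejected, so typos fail loudly instead of being
silently ignored.  CLI flags override file values, which override defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ann import TrainConfig
from .features import FeatureConfig
from .synthetic import SimConfig

__all__ = ["HMMConfig", "EvalConfig", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class HMMConfig:
    self_prob: float = 0.995
    emission_correct: float = 0.9
    start_at_first: bool = True

    def build(self):
        from .hmm import build_who_chain

        return build_who_chain(self.self_prob, self.emission_correct, self.start_at_first)


@dataclass(frozen=True)
class EvalConfig:
    k: int = 5
    seed: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    hmm: HMMConfig = field(default_factory=HMMConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)


_SECTIONS = {
    "sim": SimConfig,
    "features": FeatureConfig,
    "train": TrainConfig,
    "hmm": HMMConfig,
    "eval": EvalConfig,
}


def _build_section(cls, payload: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - valid
    if unknown:
        raise ValueError(f"unknown keys in config section '{section}': {sorted(unknown)}")
    return cls(**payload)


def load_config(path: Path | None, overrides: dict[str, dict] | None = None) -> PipelineConfig:
    """Load a pipeline config from YAML, applying per-section overrides on
    top (flags > file > defaults).  ``path=None`` starts from defaults."""
    doc: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must be a mapping of sections")
        doc = loaded
    unknown = set(doc) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    merged = {}
    overrides = overrides or {}
    for name, cls in _SECTIONS.items():
        payload = dict(doc.get(name, {}) or {})
        payload.update({k: v for k, v in (overrides.get(name, {}) or {}).items() if v is not None})
        merged[name] = _build_section(cls, payload, name)
    return PipelineConfig(**merged)
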