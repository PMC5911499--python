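"""Serializable pipeline configuration (YAML)."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .entropy import EntropyConfig
from .errors import ConfigError
from .sampling import SamplerConfig
from .synthetic import SynthConfig

DEFAULT_MODELS = ["two_factor", "survey_based", "real_time"]


def _build(cls, data: dict, context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown {context} config key(s): {sorted(unknown)}")
    # YAML represents tuples as lists; coerce where dataclasses expect tuples
    coerced = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if isinstance(val, list) and "tuple" in str(f.type):
            val = tuple(val)
        coerced[f.name] = val
    return cls(**coerced)


@dataclass
class PipelineConfig:
    """One object that reproduces a full run bit-for-bit given its seed."""

    seed: int = 0
    data_dir: str = "data"
    out_dir: str = "out"
    models: list[str] = field(default_factory=lambda: list(DEFAULT_MODELS))
    kfold_k: int = 10
    drop_unusable: bool = True
    drop_single_response: bool = True
    accuracy_rule: str = "bernoulli"
    synthetic: SynthConfig = field(default_factory=SynthConfig)
    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        sub = {
            "synthetic": SynthConfig,
            "entropy": EntropyConfig,
            "sampler": SamplerConfig,
        }
        parsed = {}
        for key, subcls in sub.items():
            if key in data:
                parsed[key] = _build(subcls, data.pop(key) or {}, key)
        allowed = {f.name for f in fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ConfigError(f"unknown pipeline config key(s): {sorted(unknown)}")
        return cls(**data, **parsed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "data_dir": self.data_dir,
            "out_dir": self.out_dir,
            "models": list(self.models),
            "kfold_k": self.kfold_k,
            "drop_unusable": self.drop_unusable,
            "drop_single_response": self.drop_single_response,
            "accuracy_rule": self.accuracy_rule,
            "synthetic": self.synthetic.to_dict(),
            "entropy": self.entropy.to_dict(),
            "sampler": self.sampler.to_dict(),
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = PipelineConfig.from_dict(self.to_dict())
        cfg.seed = seed
        cfg.synthetic.seed = seed
        cfg.sampler.seed = seed
        return cfg
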