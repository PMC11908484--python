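"""Layered YAML configuration and run manifests.

A pipeline config is a YAML mapping with per-stage sections (``simulate``,
``detect``, ``pretrain``, ``sample``, ``finetune``, ``evaluate``). Values
omitted from the file fall back to the in-code defaults, which mirror the
published hyperparameters of each stage. ``resolve_config`` returns the
fully resolved mapping, which round-trips losslessly through YAML.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .embed import ContrastiveConfig, EncoderSpec
from .finetune import FineTuneConfig
from .preprocess import DetectionConfig
from .pseudolabel import SamplingConfig
from .simulate import SimConfig

__all__ = ["ConfigError", "load_config", "resolve_config", "build_configs",
           "RunManifest"]

_STAGE_TYPES = {
    "simulate": SimConfig,
    "detect": DetectionConfig,
    "encoder": EncoderSpec,
    "pretrain": ContrastiveConfig,
    "sample": SamplingConfig,
    "finetune": FineTuneConfig,
}

#: keys that must be present (no silent default) when their stage is used
_REQUIRED = {"simulate": ["sampling_rate_hz"]}


class ConfigError(ValueError):
    """Invalid or incomplete configuration."""


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg


def _coerce(value, target):
    if isinstance(target, tuple) and isinstance(value, list):
        return tuple(value)
    return value


def resolve_config(cfg: dict) -> dict:
    """Merge user values over stage defaults; validate keys and requirements."""
    resolved: dict = {}
    for stage, typ in _STAGE_TYPES.items():
        user = cfg.get(stage, {}) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"section '{stage}' must be a mapping")
        fields = {f.name: f for f in dataclasses.fields(typ)}
        unknown = set(user) - set(fields)
        if unknown:
            raise ConfigError(
                f"unknown key(s) in '{stage}': {sorted(unknown)}")
        for key in _REQUIRED.get(stage, []):
            if stage in cfg and key not in user:
                raise ConfigError(
                    f"missing required key '{key}' in section '{stage}'")
        defaults = dataclasses.asdict(typ())
        merged = {**defaults, **{k: _coerce(v, defaults.get(k))
                                 for k, v in user.items()}}
        resolved[stage] = merged
    for key in set(cfg) - set(_STAGE_TYPES) - {"evaluate", "out_dir", "seed"}:
        raise ConfigError(f"unknown top-level section '{key}'")
    resolved["evaluate"] = {"n_runs": 1, **(cfg.get("evaluate") or {})}
    if "out_dir" in cfg:
        resolved["out_dir"] = cfg["out_dir"]
    if "seed" in cfg:
        resolved["seed"] = int(cfg["seed"])
    return resolved


def build_configs(resolved: dict) -> dict:
    """Instantiate the stage dataclasses from a resolved mapping."""
    out = {}
    for stage, typ in _STAGE_TYPES.items():
        kwargs = {k: _coerce(v, getattr(typ(), k, None))
                  for k, v in resolved[stage].items()}
        # tuples serialized as lists by YAML round trips
        for f in dataclasses.fields(typ):
            if isinstance(getattr(typ(), f.name, None), tuple) \
                    and isinstance(kwargs.get(f.name), list):
                kwargs[f.name] = tuple(kwargs[f.name])
        out[stage] = typ(**kwargs)
    return out


@dataclass
class RunManifest:
    """Provenance record written next to every pipeline artifact."""

    config: dict
    seed: int
    version: str
    stage_timings_s: dict = field(default_factory=dict)
    file_digests: dict = field(default_factory=dict)
    created: float = field(default_factory=time.time)

    def digest_file(self, name: str, path: str | Path) -> None:
        h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.file_digests[name] = h

    @property
    def manifest_hash(self) -> str:
        payload = json.dumps({"config": self.config, "seed": self.seed,
                              "version": self.version}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["manifest_hash"] = self.manifest_hash
        Path(path).write_text(json.dumps(data, indent=2, default=str))
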