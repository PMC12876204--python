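"""Declarative run configuration: loading, validation, fingerprinting.

A run config is a YAML file with up to four sections — ``generator``,
``preprocess``, ``model``, ``train`` — whose keys mirror the corresponding
dataclass fields one-to-one. Missing keys take the documented defaults;
unknown keys and invariant violations are rejected with the offending key
named. The fingerprint is a content hash of the fully-defaulted canonical
config, so it is stable under key reordering and changes whenever any
effective parameter changes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml

from .model import ModelConfig
from .synthgen import GeneratorConfig
from .train_eval import TrainConfig


@dataclass
class PreprocessParams:
    fs_preset: str = "benchmark"      # "hardware" (100 Hz) or "benchmark" (20 Hz)
    cutoff: float = 2.5
    order: int = 4
    sg_window: int = 11
    sg_polyorder: int = 3
    T: int = 200
    stride: int = 100
    filter_enabled: bool = True
    norm_scope: str = "train"         # "train" (leak-free) or "global"

    def __post_init__(self):
        if self.fs_preset not in ("hardware", "benchmark"):
            raise ValueError("preprocess.fs_preset must be 'hardware' or 'benchmark'")
        if self.norm_scope not in ("train", "global"):
            raise ValueError("preprocess.norm_scope must be 'train' or 'global'")

    @property
    def fs(self) -> float:
        return {"hardware": 100.0, "benchmark": 20.0}[self.fs_preset]


_SECTIONS = {
    "generator": GeneratorConfig,
    "preprocess": PreprocessParams,
    "model": ModelConfig,
    "train": TrainConfig,
}

# fields that are derived/non-scalar and not settable from YAML
_EXCLUDED_FIELDS = {"generator": {"rotations"}}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    generator: GeneratorConfig
    preprocess: PreprocessParams
    model: ModelConfig
    train: TrainConfig
    fingerprint: str = ""

    def canonical_dict(self) -> dict:
        out: dict = {}
        for section, cls in _SECTIONS.items():
            obj = getattr(self, section)
            sec: dict = {}
            for f in dataclasses.fields(cls):
                if f.name in _EXCLUDED_FIELDS.get(section, set()):
                    continue
                v = getattr(obj, f.name)
                if isinstance(v, tuple):
                    v = list(v)
                sec[f.name] = v
            out[section] = sec
        return out


def _coerce(section: str, key: str, value, default):
    if isinstance(default, bool):
        if not isinstance(value, bool):
            raise ConfigError(f"{section}.{key}: expected a boolean, got {value!r}")
        return value
    if isinstance(default, float) and isinstance(value, (int, float)):
        return float(value)
    if isinstance(default, int) and isinstance(value, int):
        return value
    if isinstance(default, str) and isinstance(value, str):
        return value
    if isinstance(default, tuple):
        if not isinstance(value, (list, tuple)):
            raise ConfigError(f"{section}.{key}: expected a list, got {value!r}")
        return tuple(value)
    if default is None:
        return value
    if type(default) is type(value):
        return value
    raise ConfigError(
        f"{section}.{key}: expected {type(default).__name__}, got {type(value).__name__}")


def _build_section(section: str, cls, overrides: dict):
    known = {f.name: f for f in dataclasses.fields(cls)
             if f.name not in _EXCLUDED_FIELDS.get(section, set())}
    defaults = {}
    for name, f in known.items():
        if f.default is not dataclasses.MISSING:
            defaults[name] = f.default
        elif f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
            defaults[name] = f.default_factory()            # type: ignore[misc]
        else:
            defaults[name] = None
    unknown = set(overrides) - set(known)
    if unknown:
        raise ConfigError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    kwargs = {}
    for key, value in overrides.items():
        kwargs[key] = _coerce(section, key, value, defaults[key])
    try:
        return cls(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"[{section}] {exc}") from exc


def _cross_validate(rc: RunConfig) -> None:
    m = rc.model
    if m.d_model % m.h:
        raise ConfigError(
            f"model.d_model ({m.d_model}) must be divisible by model.h ({m.h})")
    if m.d_model % m.c_attn:
        raise ConfigError(
            f"model.d_model ({m.d_model}) must be divisible by model.c_attn ({m.c_attn})")
    p = rc.preprocess
    if p.cutoff >= p.fs / 2:
        raise ConfigError(
            f"preprocess.cutoff ({p.cutoff}) must be below the Nyquist rate of "
            f"preprocess.fs_preset ({p.fs} Hz)")


def load_run_config(path_or_none=None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run config (empty/missing → all defaults)."""
    raw: dict = {}
    if path_or_none is not None:
        with open(path_or_none) as fh:
            loaded = yaml.safe_load(fh)
        raw = loaded or {}
    if overrides:
        for sec, kv in overrides.items():
            raw.setdefault(sec, {}).update(kv)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping of sections")
    unknown_sections = set(raw) - set(_SECTIONS)
    if unknown_sections:
        raise ConfigError(f"unknown section(s): {sorted(unknown_sections)}")
    sections = {}
    for name, cls in _SECTIONS.items():
        sec_raw = raw.get(name) or {}
        if not isinstance(sec_raw, dict):
            raise ConfigError(f"section [{name}] must be a mapping")
        sections[name] = _build_section(name, cls, sec_raw)
    rc = RunConfig(**sections)
    _cross_validate(rc)
    rc.fingerprint = fingerprint(rc)
    return rc


def fingerprint(rc: RunConfig) -> str:
    blob = json.dumps(rc.canonical_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
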