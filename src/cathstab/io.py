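"""Configuration loading and run provenance helpers.

Configurations are YAML (JSON accepted — every JSON file is valid YAML) and
validate against the strict pydantic models, so unknown keys fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Type, TypeVar

import yaml
from pydantic import BaseModel, ValidationError

M = TypeVar("M", bound=BaseModel)


class ConfigError(ValueError):
    """Malformed or invalid configuration file."""


def load_config(path: str | Path, model: Type[M]) -> M:
    """Load and validate a YAML/JSON configuration file."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    try:
        return model.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid config {path}:\n{exc}") from exc


def save_config(cfg: BaseModel, path: str | Path) -> None:
    Path(path).write_text(cfg.model_dump_json(indent=2) + "\n")


def config_hash(cfg: BaseModel) -> str:
    """Short stable hash of a configuration, for run logs."""
    payload = json.dumps(json.loads(cfg.model_dump_json()), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
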