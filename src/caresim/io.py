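"""Configuration files, run manifests, and CSV round-trips.

Configs are YAML mappings mirroring the dataclasses (generator fields under
``generator:``, pipeline scalars at the top level); all tables are written
as plain CSV with a header row and round-trip losslessly through pandas'
shortest-repr float formatting.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import asdict, fields

import yaml

from . import __version__
from .errors import ConfigurationError
from .pipeline import PipelineConfig
from .synthetic import GeneratorConfig

__all__ = [
    "load_pipeline_config",
    "save_pipeline_config",
    "config_digest",
    "write_manifest",
    "write_tables",
]

_PIPELINE_SCALARS = [
    f.name for f in fields(PipelineConfig) if f.name not in ("generator", "truth")
]


def _tuplify(value):
    if isinstance(value, list):
        return tuple(_tuplify(v) for v in value)
    if isinstance(value, dict):
        return {k: _tuplify(v) for k, v in value.items()}
    return value


def config_from_dict(payload: dict) -> PipelineConfig:
    payload = dict(payload)
    gen_payload = payload.pop("generator", None)
    if gen_payload is None:
        raise ConfigurationError("config must contain a 'generator' section")
    try:
        generator = GeneratorConfig(**{k: _tuplify(v) for k, v in gen_payload.items()})
    except TypeError as exc:
        raise ConfigurationError(f"invalid generator config: {exc}") from exc
    unknown = set(payload) - set(_PIPELINE_SCALARS)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(generator=generator, **payload)


def _pythonify(value):
    """Recursively convert numpy scalars/containers for YAML dumping."""
    import numpy as np

    if isinstance(value, dict):
        return {k: _pythonify(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_pythonify(v) for v in value]
    if isinstance(value, np.generic):
        return value.item()
    return value


def config_to_dict(config: PipelineConfig) -> dict:
    gen = _pythonify(asdict(config.generator))
    top = {name: _pythonify(getattr(config, name)) for name in _PIPELINE_SCALARS}
    return {"generator": gen, **top}


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise ConfigurationError(f"config file {path} is not a mapping")
    return config_from_dict(payload)


def save_pipeline_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def config_digest(config: PipelineConfig) -> str:
    text = json.dumps(config_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_manifest(out_dir, seed: int, config: PipelineConfig, **extra) -> pathlib.Path:
    """Write the run manifest (seed, config hash, version) as JSON."""
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": seed,
        "config_sha256": config_digest(config),
        "caresim_version": __version__,
        **extra,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def write_tables(out_dir, tables: dict, prefix: str = "") -> list:
    """Write a dict of DataFrames as ``<prefix><name>.csv``."""
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, frame in tables.items():
        path = out_dir / f"{prefix}{name}.csv"
        frame.to_csv(path, index=False)
        paths.append(path)
    return paths
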