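"""YAML run configuration: parsing, validation, defaults, echoing.

A run config merges the sub-configurations of every component.  Unknown
keys are rejected by name rather than silently ignored — a misspelled
key should fail loudly, not fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .losses import LossConfig
from .segnet import NetworkConfig
from .synthetic_data import PhantomConfig
from .training import StageConfig, TrainConfig

__all__ = ["RunConfig", "parse_config", "dump_config"]

_TUPLE_FIELDS = {"encoder_widths", "blocks", "decoder_widths",
                 "msa_on_skips", "msa_grids"}


@dataclass
class RunConfig:
    """Fully resolved configuration for one run."""

    seed: int = 0
    size: int = 512
    seq_len: int = 8
    threshold: float = 0.5
    output_dir: str = "runs"
    verbosity: int = 1
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)


def _build_section(cls, data: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s) under '{path}': "
            f"{', '.join(sorted(unknown))}")
    kwargs = {}
    for key, value in data.items():
        if key in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def _build_train(data: dict) -> TrainConfig:
    allowed = {f.name for f in fields(TrainConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s) under 'train': "
            f"{', '.join(sorted(unknown))}")
    kwargs = dict(data)
    for stage in ("stage1", "stage2", "stage3"):
        if stage in kwargs and isinstance(kwargs[stage], dict):
            kwargs[stage] = _build_section(StageConfig, kwargs[stage],
                                           f"train.{stage}")
    if "loss" in kwargs and isinstance(kwargs["loss"], dict):
        kwargs["loss"] = _build_section(LossConfig, kwargs["loss"],
                                        "train.loss")
    return TrainConfig(**kwargs)


def parse_config(path: str | Path | None = None,
                 overrides: list[str] | None = None) -> RunConfig:
    """Build a validated RunConfig from a YAML file and/or ``key=value``
    override strings (dotted keys address nested sections)."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        data = loaded
    for ov in overrides or []:
        if "=" not in ov:
            raise ConfigurationError(f"override '{ov}' is not key=value")
        key, _, raw = ov.partition("=")
        value = yaml.safe_load(raw)
        node = data
        parts = key.strip().split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
            if not isinstance(node, dict):
                raise ConfigurationError(f"cannot override nested key '{key}'")
        node[parts[-1]] = value

    top_allowed = {f.name for f in fields(RunConfig)}
    unknown = set(data) - top_allowed
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s): {', '.join(sorted(unknown))}")

    kwargs: dict = {k: v for k, v in data.items()
                    if k not in ("phantom", "network", "loss", "train")}
    kwargs["phantom"] = _build_section(PhantomConfig,
                                       data.get("phantom", {}), "phantom")
    kwargs["network"] = _build_section(NetworkConfig,
                                       data.get("network", {}), "network")
    kwargs["loss"] = _build_section(LossConfig, data.get("loss", {}), "loss")
    kwargs["train"] = _build_train(data.get("train", {}))
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Echo the fully resolved configuration for reproducibility."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
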