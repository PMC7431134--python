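"""Run configuration: one flat YAML/JSON file per run, strict validation.

Unknown keys are rejected and missing required fields produce
field-level messages before any compute starts.  Every run writes its
resolved configuration next to its outputs so results are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .nn.model import ModelSpec
from .nn.tiling import TilingScheme
from .nn.train import TrainingConfig
from .optics import OpticsConfig
from .phase import RegularizationConfig

SUBCOMMANDS = ("reconstruct", "phase", "simulate", "train", "predict", "evaluate")

_OPTICS_REQUIRED = ("wavelength", "na_detection", "na_illumination", "pixel_size", "z_step")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    command: str
    paths: dict = field(default_factory=dict)
    optics: OpticsConfig = None
    regularization: RegularizationConfig = None
    model: ModelSpec = None
    training: TrainingConfig = None
    tiling: TilingScheme = None
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"command": self.command, "paths": self.paths, "seed": self.seed}
        if self.optics is not None:
            out["optics"] = self.optics.to_dict()
        if self.regularization is not None:
            out["regularization"] = {
                "tau_phase": self.regularization.tau_phase,
                "tau_abs": self.regularization.tau_abs,
                "method": self.regularization.method,
                "tv_iterations": self.regularization.tv_iterations,
                "tv_beta": self.regularization.tv_beta,
                "m0_dc": self.regularization.m0_dc,
                "seed": self.regularization.seed,
            }
        if self.model is not None:
            out["model"] = self.model.to_dict()
        if self.training is not None:
            out["training"] = self.training.to_dict()
        if self.tiling is not None:
            out["tiling"] = self.tiling.to_dict()
        if self.extras:
            out.update(self.extras)
        return out


_SECTION_KEYS = {
    "command",
    "paths",
    "optics",
    "regularization",
    "model",
    "training",
    "tiling",
    "seed",
    "phantom",
    "mode",
}


def load_config(path, overrides: dict = None) -> RunConfig:
    """Parse and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    if overrides:
        payload = {**payload, **{k: v for k, v in overrides.items() if v is not None}}
    return parse_config(payload, source=str(path))


def parse_config(payload: dict, source: str = "<config>") -> RunConfig:
    unknown = set(payload) - _SECTION_KEYS
    if unknown:
        raise ConfigError(f"{source}: unknown keys {sorted(unknown)}")
    command = payload.get("command")
    if command not in SUBCOMMANDS:
        raise ConfigError(
            f"{source}: field 'command' must be one of {SUBCOMMANDS}, got {command!r}"
        )

    optics = None
    if "optics" in payload:
        section = dict(payload["optics"])
        missing = [k for k in _OPTICS_REQUIRED if k not in section]
        if missing:
            raise ConfigError(f"{source}: optics section missing field(s) {missing}")
        try:
            optics = OpticsConfig(**section)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{source}: optics: {exc}") from exc
    elif command in ("reconstruct", "phase", "simulate"):
        raise ConfigError(f"{source}: command {command!r} requires an 'optics' section")

    def _build(name, cls):
        if name not in payload:
            return None
        try:
            return cls(**payload[name])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{source}: {name}: {exc}") from exc

    reg = _build("regularization", RegularizationConfig)
    tiling = _build("tiling", TilingScheme)
    training = _build("training", TrainingConfig)
    model = None
    if "model" in payload:
        try:
            model = ModelSpec.from_dict(payload["model"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{source}: model: {exc}") from exc

    extras = {k: payload[k] for k in ("phantom", "mode") if k in payload}
    return RunConfig(
        command=command,
        paths=dict(payload.get("paths", {})),
        optics=optics,
        regularization=reg,
        model=model,
        training=training,
        tiling=tiling,
        seed=int(payload.get("seed", 0)),
        extras=extras,
    )


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
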