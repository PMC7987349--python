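"""Run configuration: YAML-backed, schema-validated, hashable.

A run configuration bundles the acquisition, mirror, transducer, phantom
and reconstruction sections.  The packaged default profile matches the
reference operating point of the hardware study this toolkit models
(20-kHz PRF, 250-Hz mirror, 15.625-MHz 128-element array, 2.1-mm
transducer-to-mirror spacing, 500-Hz volume rate).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .acoustic import TransducerModel
from .scheduler import AcquisitionConfig, MirrorKinematics

__all__ = ["ConfigError", "RunConfig", "default_config", "load_config", "save_config"]


class ConfigError(ValueError):
    """Raised when a configuration file fails validation."""


_SECTIONS = {
    "acquisition": AcquisitionConfig,
    "mirror": MirrorKinematics,
    "transducer": TransducerModel,
}


@dataclass
class RunConfig:
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    mirror: MirrorKinematics = field(
        default_factory=lambda: MirrorKinematics(11.95, 250.0)
    )
    transducer: TransducerModel = field(default_factory=TransducerModel)
    phantom: dict = field(default_factory=lambda: {"type": "wire"})
    reconstruction: dict = field(
        default_factory=lambda: {"spacing_mm": 0.1, "dyn_range_db": 40.0}
    )
    seed: int = 0
    output_dir: str = "runs"

    def to_dict(self) -> dict:
        return {
            "acquisition": dataclasses.asdict(self.acquisition),
            "mirror": dataclasses.asdict(self.mirror),
            "transducer": dataclasses.asdict(self.transducer),
            "phantom": dict(self.phantom),
            "reconstruction": dict(self.reconstruction),
            "seed": self.seed,
            "output_dir": self.output_dir,
        }


def _build_section(name: str, cls, payload: dict, errors: list[str]):
    if not isinstance(payload, dict):
        errors.append(f"section '{name}' must be a mapping")
        return None
    valid_fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - valid_fields
    if unknown:
        errors.append(f"section '{name}' has unknown keys: {sorted(unknown)}")
        return None
    try:
        return cls(**payload)
    except (TypeError, ValueError) as exc:
        errors.append(f"section '{name}': {exc}")
        return None


def config_from_dict(raw: dict) -> RunConfig:
    """Validate a raw mapping into a RunConfig, collecting all problems."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    errors: list[str] = []
    known = set(_SECTIONS) | {"phantom", "reconstruction", "seed", "output_dir"}
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            obj = _build_section(name, cls, raw[name], errors)
            if obj is not None:
                kwargs[name] = obj
    for name in ("phantom", "reconstruction"):
        if name in raw:
            if not isinstance(raw[name], dict):
                errors.append(f"section '{name}' must be a mapping")
            else:
                kwargs[name] = raw[name]
    if "seed" in raw:
        if not isinstance(raw["seed"], int):
            errors.append("seed must be an integer")
        else:
            kwargs["seed"] = raw["seed"]
    if "output_dir" in raw:
        kwargs["output_dir"] = str(raw["output_dir"])
    if errors:
        raise ConfigError("; ".join(errors))
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return config_from_dict(raw or {})


def save_config(path, cfg: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def default_config() -> RunConfig:
    """The packaged reference profile."""
    text = (
        importlib.resources.files("tiltscan") / "data" / "default.yaml"
    ).read_text()
    return config_from_dict(yaml.safe_load(text))
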