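"""YAML run configuration: strict parsing into the module dataclasses.

A run config is a YAML mapping with optional sections ``windowing``,
``augmentation``, ``model``, ``loss``, ``pretrain`` and ``evaluate``;
unknown sections or keys are rejected outright (listing every offending
key) so typos never silently fall back to defaults. Every CLI run writes
its resolved config next to its outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import PRESETS as AUG_PRESETS
from .augment import AugmentationConfig
from .evaluate import EvalConfig
from .losses import LossConfig
from .model import ModelSpec
from .pretrain import PretrainConfig
from .segments import WindowingConfig

__all__ = ["RunConfig", "load_run_config", "resolve_run_config", "dump_resolved"]


@dataclass
class RunConfig:
    windowing: WindowingConfig = field(default_factory=WindowingConfig)
    augmentation: AugmentationConfig = field(
        default_factory=lambda: AUG_PRESETS["hasc_like"]
    )
    model: ModelSpec = field(default_factory=ModelSpec)
    loss: LossConfig = field(default_factory=LossConfig)
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    evaluate: EvalConfig = field(default_factory=EvalConfig)

    def __post_init__(self) -> None:
        # pretrain carries the augmentation and loss sub-configs with it
        self.pretrain = dataclasses.replace(
            self.pretrain, augmentation=self.augmentation, loss=self.loss
        )


_SECTIONS = {
    "windowing": WindowingConfig,
    "augmentation": AugmentationConfig,
    "model": ModelSpec,
    "loss": LossConfig,
    "pretrain": PretrainConfig,
    "evaluate": EvalConfig,
}


def _build_section(name: str, cls, raw: dict, errors: list[str]):
    if name == "augmentation" and isinstance(raw, str):
        if raw not in AUG_PRESETS:
            errors.append(f"augmentation: unknown preset {raw!r}")
            return None
        return AUG_PRESETS[raw]
    fields = {f.name for f in dataclasses.fields(cls)}
    skip = {"augmentation", "loss"} if cls is PretrainConfig else set()
    unknown = set(raw) - fields
    for key in sorted(unknown):
        errors.append(f"{name}: unknown key {key!r}")
    kwargs = {k: v for k, v in raw.items() if k in fields - skip}
    if cls is ModelSpec and "channels" in kwargs:
        kwargs["channels"] = tuple(kwargs["channels"])
    if unknown:
        return None
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{name}: {exc}")
        return None


def resolve_run_config(raw: dict | None) -> RunConfig:
    """Validate a raw YAML mapping into a :class:`RunConfig`."""
    raw = raw or {}
    errors: list[str] = []
    for key in sorted(set(raw) - set(_SECTIONS)):
        errors.append(f"unknown section {key!r}")
    sections = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            built = _build_section(name, cls, raw[name], errors)
            if built is not None:
                sections[name] = built
    if errors:
        raise ValueError("invalid run config:\n  " + "\n  ".join(errors))
    return RunConfig(**sections)


def load_run_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        return resolve_run_config(yaml.safe_load(fh))


def dump_resolved(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved config (all defaults filled in) as YAML."""
    out = {}
    for name in _SECTIONS:
        section = dataclasses.asdict(getattr(config, name))
        section.pop("augmentation", None)
        section.pop("loss", None)
        out[name] = section
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=True)
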