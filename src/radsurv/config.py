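"""Pipeline configuration: defaults, YAML parsing and validation.

The YAML layout mirrors the pipeline stages; unknown keys are rejected
and every threshold is range-checked, each violation reported with its
key path. ``PipelineConfig`` round-trips losslessly through
``to_dict`` / ``from_dict``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import DiscretizationSpec, FilterBank
from .phantom import HazardSpec, PhantomSpec
from .stability import PerturbationSpec

__all__ = ["PipelineConfig", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid configuration; carries one message per violation."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n" + "\n".join(f"  - {e}" for e in errors))


@dataclass(frozen=True)
class Thresholds:
    icc1: float = 0.7
    icc2: float = 0.95
    alpha: float = 0.05
    n_components: int = 5


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one reproducible end-to-end run depends on."""

    n_patients: int = 40
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    hazard: HazardSpec = field(default_factory=HazardSpec)
    disc_ct: DiscretizationSpec = field(default_factory=lambda: DiscretizationSpec(bin_width=25.0))
    disc_dose: DiscretizationSpec = field(default_factory=lambda: DiscretizationSpec(bin_width=0.5))
    filter_bank: FilterBank | None = field(default_factory=FilterBank)
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    thresholds: Thresholds = field(default_factory=Thresholds)
    screen_before_pca: bool = False
    icc1_formula: str = "as_printed"
    c_index_tie_mode: str = "half"

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        return clean(dataclasses.asdict(self))

    @staticmethod
    def from_dict(data: dict) -> "PipelineConfig":
        errors: list[str] = []
        cfg = _build(data, errors)
        if errors:
            raise ConfigError(errors)
        return cfg


_SECTIONS = {
    "phantom": PhantomSpec,
    "hazard": HazardSpec,
    "disc_ct": DiscretizationSpec,
    "disc_dose": DiscretizationSpec,
    "filter_bank": FilterBank,
    "perturbation": PerturbationSpec,
    "thresholds": Thresholds,
}
_SCALARS = {
    "n_patients",
    "seed",
    "screen_before_pca",
    "icc1_formula",
    "c_index_tie_mode",
}


def _coerce(cls, raw: dict, path: str, errors: list[str]):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - allowed
    for key in sorted(unknown):
        errors.append(f"{path}.{key}: unknown key")
    kwargs = {}
    for key, val in raw.items():
        if key in allowed:
            kwargs[key] = tuple(val) if isinstance(val, list) else val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{path}: {exc}")
        return cls()


def _build(data: dict, errors: list[str]) -> "PipelineConfig":
    if not isinstance(data, dict):
        errors.append("top level: config must be a mapping")
        return PipelineConfig()
    unknown = set(data) - set(_SECTIONS) - _SCALARS
    for key in sorted(unknown):
        errors.append(f"{key}: unknown key")
    kwargs = {}
    for key in _SCALARS & set(data):
        kwargs[key] = data[key]
    for key, cls in _SECTIONS.items():
        if key in data:
            if key == "filter_bank" and data[key] is None:
                kwargs[key] = None
            else:
                kwargs[key] = _coerce(cls, data[key] or {}, key, errors)
    cfg = PipelineConfig(**{k: v for k, v in kwargs.items()})

    th = cfg.thresholds
    checks = [
        (0 <= th.icc1 <= 1, "thresholds.icc1: must be in [0, 1]"),
        (0 <= th.icc2 <= 1, "thresholds.icc2: must be in [0, 1]"),
        (0 < th.alpha < 1, "thresholds.alpha: must be in (0, 1)"),
        (th.n_components >= 1, "thresholds.n_components: must be >= 1"),
        (cfg.n_patients >= 2, "n_patients: must be >= 2"),
        (cfg.icc1_formula in ("as_printed", "standard"),
         "icc1_formula: must be 'as_printed' or 'standard'"),
        (cfg.c_index_tie_mode in ("half", "strict"),
         "c_index_tie_mode: must be 'half' or 'strict'"),
    ]
    for ok, msg in checks:
        if not ok:
            errors.append(msg)
    return cfg


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and range-check a YAML config file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    return PipelineConfig.from_dict(data)


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
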