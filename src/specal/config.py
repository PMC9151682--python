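"""Pipeline configuration: a validated YAML schema and seed derivation.

A single global seed deterministically derives a sub-seed for every stage
(synthetic generation, pool splitting, learner subsampling, ...) through
``numpy.random.SeedSequence([global_seed, stage_index])``, so changing the
output directory or re-running never changes a number.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .active import ALConfig
from .boosting import BoostParams
from .exceptions import ConfigError
from .preprocess import SmoothSpec
from .synthetic import (
    DEFAULT_N_BANDS,
    DEFAULT_N_CLASSES,
    DEFAULT_N_PER_CLASS,
    DEFAULT_WAVELENGTH_RANGE,
)

__all__ = ["PipelineConfig", "SyntheticConfig", "PreprocessConfig",
           "ManifoldConfig", "load_config", "stage_seed"]

# stable stage indices for seed derivation
STAGES = {"synthetic": 0, "pools": 1, "boosting": 2, "runs": 3}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stage sub-seed (< 2**31) from the global seed."""
    return int(np.random.SeedSequence(
        [int(global_seed), STAGES[stage]]).generate_state(1)[0] % 2**31)


@dataclass
class SyntheticConfig:
    n_classes: int = DEFAULT_N_CLASSES
    n_bands: int = DEFAULT_N_BANDS
    n_per_class: int = DEFAULT_N_PER_CLASS
    wavelength_low: float = DEFAULT_WAVELENGTH_RANGE[0]
    wavelength_high: float = DEFAULT_WAVELENGTH_RANGE[1]
    additive_offset_sd: float = 0.02
    multiplicative_slope_low: float = 0.8
    multiplicative_slope_high: float = 1.2
    noise_sd: float = 0.01


@dataclass
class PreprocessConfig:
    half_width: int = 2
    kind: str = "uniform"

    def smooth_spec(self) -> SmoothSpec:
        return SmoothSpec(half_width=self.half_width, kind=self.kind)


@dataclass
class ManifoldConfig:
    k: int = 10
    n_components: int | str = "auto"   # "auto" scans z_min..z_max by RMSE
    z_min: int = 1
    z_max: int = 20
    on_disconnected: str = "bridge"


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "runs"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    manifold: ManifoldConfig = field(default_factory=ManifoldConfig)
    boosting: BoostParams = field(default_factory=lambda: BoostParams(
        n_classes=DEFAULT_N_CLASSES))
    active: ALConfig = field(default_factory=ALConfig)

    def resolved_yaml(self) -> str:
        payload = asdict(self)
        payload["boosting"] = vars(self.boosting).copy()
        payload["active"] = vars(self.active).copy()
        return yaml.safe_dump(payload, sort_keys=False)

    def dump(self, path) -> None:
        Path(path).write_text(self.resolved_yaml(), encoding="utf-8")


def _build_section(cls, payload: dict, section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(payload) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{section}'")
    try:
        return cls(**payload)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{section}': {exc}") from exc


def load_config(source=None, overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected.

    ``source`` is a path, stream, or None (all defaults); ``overrides``
    is a shallow dict applied on top (e.g. a CLI ``--seed``).
    """
    payload: dict = {}
    if source is not None:
        if isinstance(source, (str, Path)):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = source.read()
        payload = yaml.safe_load(text) or {}
        if not isinstance(payload, dict):
            raise ConfigError("config root must be a mapping")
    payload = {**payload, **(overrides or {})}

    sections = {
        "synthetic": SyntheticConfig,
        "preprocess": PreprocessConfig,
        "manifold": ManifoldConfig,
        "boosting": BoostParams,
        "active": ALConfig,
    }
    known_top = set(sections) | {"seed", "outdir"}
    unknown = set(payload) - known_top
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")

    kwargs: dict = {
        "seed": int(payload.get("seed", 0)),
        "outdir": str(payload.get("outdir", "runs")),
    }
    for name, cls in sections.items():
        section_payload = payload.get(name, {}) or {}
        if not isinstance(section_payload, dict):
            raise ConfigError(f"section '{name}' must be a mapping")
        kwargs[name] = _build_section(cls, dict(section_payload), name)
    config = PipelineConfig(**kwargs)
    # stitch derived seeds so every stage is reproducible from the global one
    config.active = ALConfig(**{**vars(config.active),
                                "seed": stage_seed(config.seed, "pools"),
                                "batch_size": None})
    config.boosting = BoostParams(**{**vars(config.boosting),
                                     "seed": stage_seed(config.seed,
                                                        "boosting")})
    return config
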