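"""Pipeline configuration: one YAML file driving every stage.

The schema is a nested mapping with sections ``sim``, ``preprocess``,
``ren``, ``taxonomy``, ``cv`` plus a global ``seed``; unknown keys anywhere
are rejected. Stage seeds are derived deterministically from the global
seed by fixed offsets so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .predict import CVConfig
from .preprocess import NEAR_WINDOW_S, SEGMENT_LEN_S, BandSpec, MontageLayout
from .ren import RENConfig
from .synthetic import SimConfig
from .taxonomy import TaxonomyConfig

#: Fixed per-stage seed offsets (documented derivation scheme).
STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "predict": 1,
    "sweep": 2,
}


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) + STAGE_SEED_OFFSETS[stage]) % (2**31)


@dataclass(frozen=True)
class PreprocessConfig:
    near_window_s: float = NEAR_WINDOW_S
    segment_len_s: float = SEGMENT_LEN_S

    def __post_init__(self) -> None:
        if not 0 < self.segment_len_s <= self.near_window_s:
            raise ValueError("need 0 < segment_len_s <= near_window_s")


@dataclass(frozen=True)
class PipelineConfig:
    """All module configs plus the global seed."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    ren: RENConfig = field(default_factory=RENConfig)
    taxonomy: TaxonomyConfig = field(default_factory=TaxonomyConfig)
    cv: CVConfig = field(default_factory=CVConfig)

    def __post_init__(self) -> None:
        # propagate the global seed into the stage configs
        object.__setattr__(
            self, "sim", dataclasses.replace(self.sim, seed=stage_seed(self.seed, "simulate"))
        )
        object.__setattr__(
            self, "cv", dataclasses.replace(self.cv, seed=stage_seed(self.seed, "predict"))
        )

    @property
    def bands(self) -> tuple[BandSpec, ...]:
        return self.sim.bands


def _build(cls, data: Mapping[str, Any], path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) in {path}: {sorted(unknown)}")
    kwargs = dict(data)
    # nested structured fields
    if cls is SimConfig:
        if "layout" in kwargs:
            kwargs["layout"] = _build(MontageLayout, kwargs["layout"], f"{path}.layout")
        if "bands" in kwargs:
            kwargs["bands"] = tuple(
                BandSpec(**b) for b in kwargs["bands"]
            )
        for tup in ("effect_bands", "duration_range_s", "ictal_gain"):
            if tup in kwargs:
                kwargs[tup] = tuple(kwargs[tup])
    if cls is CVConfig and "models" in kwargs:
        kwargs["models"] = tuple(kwargs["models"])
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a pipeline YAML file (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ValueError("pipeline config must be a mapping")
    sections = {"seed", "sim", "preprocess", "ren", "taxonomy", "cv"}
    unknown = set(raw) - sections
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {"seed": int(raw.get("seed", 0))}
    for name, cls in (
        ("sim", SimConfig),
        ("preprocess", PreprocessConfig),
        ("ren", RENConfig),
        ("taxonomy", TaxonomyConfig),
        ("cv", CVConfig),
    ):
        if name in raw:
            kwargs[name] = _build(cls, raw[name] or {}, name)
    return PipelineConfig(**kwargs)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def dump_resolved(cfg: PipelineConfig, path: str | Path) -> None:
    """Write the fully resolved config next to the outputs (JSON)."""
    Path(path).write_text(json.dumps(_jsonable(cfg), indent=1, default=str))


def config_fingerprint(obj: Any) -> str:
    """Stable hash of any config object, for the stage manifest."""
    import hashlib

    return hashlib.sha256(
        json.dumps(_jsonable(obj), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
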