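"""Run configuration: a validated schema for the analysis pipeline.

The configuration is strict JSON: unknown keys are rejected, so typos fail
fast instead of silently falling back to defaults.  Units are Å, kcal/mol,
kcal/mol/Å² and K throughout.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PotentialConfig(_Strict):
    """Landmark nodes of the analytic surrogate free-energy surface."""

    nodes: list[tuple[float, float]] = [(1.5, 0.0), (2.17, 19.0), (3.2, 5.0)]
    stationary: list[bool] | None = None
    wall_k: float = Field(default=100.0, gt=0)


class UmbrellaConfig(_Strict):
    n_windows: int = Field(default=42, ge=2)
    rc_range: tuple[float, float] = (1.3, 3.5)
    k: float = Field(default=500.0, gt=0)
    dt: float = Field(default=0.1, gt=0)
    D: float = Field(default=0.001, gt=0)
    n_equil: int = Field(default=10_000, ge=0)
    n_prod: int = Field(default=10_000, ge=1)
    bias_factor: float = Field(default=0.5, gt=0)


class WhamConfig(_Strict):
    bin_width: float = Field(default=0.02, gt=0)
    tol: float = Field(default=1e-7, gt=0)
    max_iter: int = Field(default=100_000, ge=1)


class LandmarkConfig(_Strict):
    reactant_window: tuple[float, float] = (1.3, 1.9)
    product_window: tuple[float, float] = (2.9, 3.5)


class RingConfig(_Strict):
    radius: float = Field(default=1.45, gt=0)
    n_frames: int = Field(default=2000, ge=1)
    rc2_range: tuple[float, float] = (1.4, 3.3)
    anchors: list[tuple[float, float, float, float]] = [
        (1.5, 0.57, 90.0, 210.0),
        (2.0, 0.55, 90.0, 210.0),
        (2.1, 0.45, 90.0, 120.0),
        (2.3, 0.45, 90.0, 120.0),
        (2.5, 0.57, 0.0, 0.0),
    ]
    angle_noise_sd: float = Field(default=8.0, ge=0)
    q_noise_sd: float = Field(default=0.03, ge=0)


class RCTermConfig(_Strict):
    a: str
    b: str
    w: float


class RCSpecConfig(_Strict):
    name: str
    terms: list[RCTermConfig]


class RunConfig(_Strict):
    """Full pipeline configuration (validated before any stage runs)."""

    seed: int = Field(default=1, ge=0, lt=2**31)
    temperature: float = Field(default=300.0, gt=0)
    outdir: str = "out"
    potential: PotentialConfig = PotentialConfig()
    umbrella: UmbrellaConfig = UmbrellaConfig()
    wham: WhamConfig = WhamConfig()
    landmarks: LandmarkConfig = LandmarkConfig()
    regions: dict[str, tuple[float, float]] = {
        "reactant": (1.5, 1.8),
        "ts": (2.0, 2.3),
        "product": (2.4, 3.2),
    }
    ring: RingConfig = RingConfig()
    rcspecs: list[RCSpecConfig] = []

    @model_validator(mode="after")
    def _check_ranges(self) -> "RunConfig":
        if self.umbrella.rc_range[0] >= self.umbrella.rc_range[1]:
            raise ValueError("umbrella.rc_range must be increasing")
        for name, (lo, hi) in self.regions.items():
            if lo > hi:
                raise ValueError(f"region {name!r}: interval must satisfy lo <= hi")
        return self


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a JSON config file; ``None`` yields the defaults."""
    if path is None:
        return RunConfig()
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        return RunConfig.model_validate(doc)
    except ValidationError as exc:
        raise ConfigError(f"invalid config {path}:\n{exc}") from exc


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the resolved configuration, for provenance headers."""
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
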