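"""Run configuration: schema, loading, defaults and test fixtures.

A run is fully described by a YAML document; every omitted field falls back
to the baseline study conditions (mu_a = 0.10 mm^-1, mu_s = 6.86 mm^-1,
12 x 6 mm slab, indices 1.59/1.33, lambda = 1000 nm).  Unknown keys are
rejected and all schema violations are reported together.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__ as _version
from .mc import DetectorRegion, MediumOptics, SlabGeometry

__all__ = ["RunConfig", "load_config", "dump_config", "make_fixture", "ConfigError"]


class ConfigError(ValueError):
    """Configuration file failed validation; message lists every bad field."""


class MediumConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mu_a: float = Field(default=0.10, ge=0)
    mu_s: float = Field(default=6.86, gt=0)
    n_particle: float = Field(default=1.59, gt=0)
    n_medium: float = Field(default=1.33, gt=0)
    particle_diameter_um: float = Field(default=9.0, gt=0)
    wavelength_nm: float = Field(default=1000.0, gt=0)


class SlabConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    width_mm: float = Field(default=12.0, gt=0)
    depth_mm: float = Field(default=6.0, gt=0)


class DetectorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    side: Literal["reflection", "transmission"]
    x_range_mm: tuple[float, float] | None = None
    z_half_width_mm: float = Field(default=1.0, gt=0)


class RunConfig(BaseModel):
    """Validated configuration for one polarized MC run."""

    model_config = ConfigDict(extra="forbid")
    medium: MediumConfig = MediumConfig()
    slab: SlabConfig = SlabConfig()
    detectors: list[DetectorConfig] = [
        DetectorConfig(side="reflection"),
        DetectorConfig(side="transmission"),
    ]
    photons: int = Field(default=20_000, gt=0)
    seed: int = 0
    incident_angle_deg: float = 1.0
    output_dir: str = "."

    def medium_optics(self) -> MediumOptics:
        return MediumOptics(**self.medium.model_dump())

    def slab_geometry(self) -> SlabGeometry:
        return SlabGeometry(**self.slab.model_dump())

    def detector_regions(self) -> list[DetectorRegion]:
        out = []
        for d in self.detectors:
            kwargs = {"side": d.side, "z_half_width_mm": d.z_half_width_mm}
            if d.x_range_mm is not None:
                kwargs["x_range_mm"] = tuple(d.x_range_mm)
            out.append(DetectorRegion(**kwargs))
        return out

    def provenance(self) -> dict:
        """Config hash + seed + version block written next to every output."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=list)
        return {
            "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
            "seed": self.seed,
            "version": _version,
        }


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (empty file = all defaults)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        fields = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        )
        raise ConfigError(f"invalid configuration {path}: {fields}") from err


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(), sort_keys=True, default_flow_style=False)
    )


def make_fixture(profile: str) -> RunConfig:
    """Small, fast configurations for tests and smoke runs.

    ``smoke`` — default medium, 1000 photons;
    ``thin_slab`` — ballistic transmission limit, mu_s * depth = 0.05;
    ``rayleigh`` — X = 0.1 particle (a = 0.1 um at 1000 nm).
    """
    if profile == "smoke":
        return RunConfig(photons=1000)
    if profile == "thin_slab":
        return RunConfig(
            medium=MediumConfig(mu_s=0.05 / 6.0, mu_a=0.0),
            detectors=[
                DetectorConfig(side="transmission", x_range_mm=(-6.0, 6.0),
                               z_half_width_mm=1e9)
            ],
            photons=2000,
        )
    if profile == "rayleigh":
        return RunConfig(
            medium=MediumConfig(particle_diameter_um=0.1),
            photons=2000,
        )
    raise ValueError(f"unknown fixture profile {profile!r}")
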