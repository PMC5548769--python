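"""Pipeline configuration: YAML-backed, validated, with protocol defaults.

Defaults mirror the acquisition protocol the simulator models (2 um pixels,
15 cm propagation distance, 25 keV, delta/beta = 300, 2400 projections over
360 degrees). Unknown keys are rejected so typos cannot silently fall back
to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError


def _check(cond: bool, name: str, constraint: str) -> None:
    if not cond:
        raise ConfigError(f"invalid config value for {name!r}: {constraint}")


@dataclass
class GeometryBlock:
    pixel_size_um: float = 2.0
    distance_cm: float = 15.0
    energy_keV: float = 25.0
    n_projections: int = 2400
    angular_range_deg: int = 360
    fov_offset_px: int = 0
    exposure_ms: float = 600.0  # provenance only

    def validate(self) -> None:
        _check(self.pixel_size_um > 0, "geometry.pixel_size_um", "must be > 0")
        _check(self.distance_cm >= 0, "geometry.distance_cm", "must be >= 0")
        _check(self.energy_keV > 0, "geometry.energy_keV", "must be > 0")
        _check(self.n_projections >= 1, "geometry.n_projections", "must be >= 1")
        _check(self.angular_range_deg in (180, 360),
               "geometry.angular_range_deg", "must be 180 or 360")
        _check(self.fov_offset_px >= 0, "geometry.fov_offset_px", "must be >= 0")


@dataclass
class RetrievalBlock:
    delta_beta: float = 300.0

    def validate(self) -> None:
        _check(self.delta_beta >= 0, "retrieval.delta_beta", "must be >= 0")


@dataclass
class SegmentationBlock:
    median_radius: int = 1
    n_bins: int = 256
    min_voxels: int = 27

    def validate(self) -> None:
        _check(self.median_radius >= 0, "segmentation.median_radius", "must be >= 0")
        _check(self.n_bins >= 2, "segmentation.n_bins", "must be >= 2")
        _check(self.min_voxels >= 1, "segmentation.min_voxels", "must be >= 1")


@dataclass
class ErosionBlock:
    target_bvtv_drop: float = 0.11
    removal_prob: float = 0.2
    max_iters: int = 200

    def validate(self) -> None:
        _check(0 <= self.target_bvtv_drop < 1,
               "phantom.erosion.target_bvtv_drop", "must be in [0, 1)")
        _check(0 < self.removal_prob <= 1,
               "phantom.erosion.removal_prob", "must be in (0, 1]")
        _check(self.max_iters >= 1, "phantom.erosion.max_iters", "must be >= 1")


@dataclass
class PhantomBlock:
    shape: str = "pyramid"
    size_params: dict = field(default_factory=dict)  # empty -> shape defaults
    voxel_size_um: float = 2.0
    cavity_fraction: float = 0.25
    n_per_group: int = 3
    between_animal_cv: float = 0.05
    erosion: ErosionBlock = field(default_factory=ErosionBlock)

    def validate(self) -> None:
        _check(self.shape in ("sphere", "pyramid", "lunula"),
               "phantom.shape", "must be sphere, pyramid or lunula")
        _check(self.voxel_size_um > 0, "phantom.voxel_size_um", "must be > 0")
        _check(0 <= self.cavity_fraction < 1,
               "phantom.cavity_fraction", "must be in [0, 1)")
        _check(self.n_per_group >= 2, "phantom.n_per_group", "must be >= 2")
        _check(self.between_animal_cv >= 0,
               "phantom.between_animal_cv", "must be >= 0")
        self.erosion.validate()


@dataclass
class SimulationBlock:
    mu_bone_mm: float = 0.15
    mu_background_mm: float = 0.01
    mean_counts: float = 1.0e5
    read_noise_counts: float = 1.0
    flat_value: float = 1.0
    use_extended_fov: bool = False

    def validate(self) -> None:
        _check(self.mu_bone_mm > self.mu_background_mm >= 0,
               "simulation.mu_bone_mm", "must exceed mu_background_mm >= 0")
        _check(self.mean_counts > 0, "simulation.mean_counts", "must be > 0")
        _check(self.flat_value > 0, "simulation.flat_value", "must be > 0")


@dataclass
class PipelineConfig:
    geometry: GeometryBlock = field(default_factory=GeometryBlock)
    retrieval: RetrievalBlock = field(default_factory=RetrievalBlock)
    segmentation: SegmentationBlock = field(default_factory=SegmentationBlock)
    phantom: PhantomBlock = field(default_factory=PhantomBlock)
    simulation: SimulationBlock = field(default_factory=SimulationBlock)
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        for block in (self.geometry, self.retrieval, self.segmentation,
                      self.phantom, self.simulation):
            block.validate()
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path or 'config'} must be a mapping")
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} under {path or 'top level'}"
        )
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        sub = f.type if isinstance(f.type, type) else None
        default = getattr(cls(), name)
        if dataclasses.is_dataclass(default) and not isinstance(value, default.__class__):
            kwargs[name] = _build(default.__class__, value, f"{path}.{name}".strip("."))
        else:
            kwargs[name] = value
    return cls(**kwargs)


def config_from_dict(data: dict | None) -> PipelineConfig:
    cfg = _build(PipelineConfig, data or {}, "")
    return cfg.validate()


def load_config(path) -> PipelineConfig:
    """Parse and validate a YAML config; an empty file yields all defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def dump_config(cfg: PipelineConfig, path=None) -> str:
    text = yaml.safe_dump(cfg.to_dict(), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
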