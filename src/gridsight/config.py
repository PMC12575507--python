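"""Configuration schema (YAML) tying the pipeline stages together.

The schema is validated strictly: unknown keys are rejected, units are
meters and pixels, and cross-field constraints (positive baseline,
integer upscale factor >= 1, ...) are checked before any stage runs.
A minimal config containing only a seed expands to the full default
pipeline.
"""

from __future__ import annotations

import hashlib

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from ._errors import ConfigError
from .camera import CameraIntrinsics, DistortionCoeffs, RigidPose, StereoRig
from .evaluation import ExperimentSpec
from .grid import GridSpec
from .render import RenderSettings
from .scenes import MeasurementLayout

__all__ = ["PipelineConfig", "validate_config", "serialize_config", "config_hash"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RigConfig(_Block):
    """Stereo rig; fx/fy/cx/cy default to the symmetric `focal`-based rig."""

    width: int = Field(640, gt=0)
    height: int = Field(480, gt=0)
    focal: float = Field(550.0, description="focal length, pixels")
    baseline: float = Field(0.098, description="stereo baseline, meters")
    distortion_left: list[float] = Field(default_factory=lambda: [0.0] * 5)
    distortion_right: list[float] = Field(default_factory=lambda: [0.0] * 5)

    @field_validator("focal")
    @classmethod
    def _focal_positive(cls, v):
        if v <= 0:
            raise ValueError("focal length must be positive pixels")
        return v

    @field_validator("baseline")
    @classmethod
    def _baseline_positive(cls, v):
        if v <= 0:
            raise ValueError("baseline must be positive meters")
        return v

    @field_validator("distortion_left", "distortion_right")
    @classmethod
    def _five_coeffs(cls, v):
        if len(v) != 5:
            raise ValueError("distortion needs 5 coefficients (k1 k2 k3 p1 p2)")
        return v

    def to_rig(self) -> StereoRig:
        intr = CameraIntrinsics(
            self.focal, self.focal, (self.width - 1) / 2.0, (self.height - 1) / 2.0,
            self.width, self.height,
        )
        return StereoRig(
            left=intr, right=intr,
            dist_left=DistortionCoeffs(*self.distortion_left),
            dist_right=DistortionCoeffs(*self.distortion_right),
            right_in_left=RigidPose(np.eye(3), np.array([self.baseline, 0.0, 0.0])),
        )


class GridConfig(_Block):
    rows: int = Field(8, ge=1)
    cols: int = Field(8, ge=1)
    pitch: float = Field(0.005, gt=0, description="inter-electrode distance, meters")
    disk_diameter: float = Field(0.004, gt=0)
    n_tails: int = Field(4, ge=0)

    def to_spec(self) -> GridSpec:
        return GridSpec(rows=self.rows, cols=self.cols, pitch=self.pitch,
                        disk_diameter=self.disk_diameter, n_tails=self.n_tails)


class RenderConfig(_Block):
    background_mode: str = "flat"
    background_range: tuple[float, float] = (0.05, 0.25)
    ambient: float = Field(0.7, ge=0, le=1)
    disk_intensity: float = Field(0.85, ge=0, le=1)
    disk_sigma: float = Field(0.04, ge=0)
    sheet_intensity: float = Field(0.50, ge=0, le=1)
    sheet_sigma: float = Field(0.04, ge=0)
    blur_sigma: float = Field(0.6, ge=0)
    noise_sigma: float = Field(0.01, ge=0)

    def to_settings(self, seed: int = 0) -> RenderSettings:
        return RenderSettings(
            background_mode=self.background_mode,
            background_range=tuple(self.background_range),
            ambient=self.ambient,
            disk_intensity=self.disk_intensity, disk_sigma=self.disk_sigma,
            sheet_intensity=self.sheet_intensity, sheet_sigma=self.sheet_sigma,
            blur_sigma=self.blur_sigma, noise_sigma=self.noise_sigma, seed=seed,
        )


class DetectorConfig(_Block):
    kind: str = "classical"  # oracle | classical | external
    jitter_px: float = Field(0.0, ge=0)
    threshold: float | None = None
    min_area: int = Field(60, ge=1)

    @field_validator("kind")
    @classmethod
    def _known(cls, v):
        if v not in ("oracle", "classical", "external"):
            raise ValueError(f"unknown detector kind {v!r}")
        return v


class UpscalerConfig(_Block):
    kind: str = "bicubic"  # bicubic | external
    factor: int = Field(4, ge=1)

    @field_validator("kind")
    @classmethod
    def _known(cls, v):
        if v not in ("bicubic", "external"):
            raise ValueError(f"unknown upscaler kind {v!r}")
        return v


class PoseConfig(_Block):
    kind: str = "classical"  # classical | oracle
    noise_px: float = Field(0.0, ge=0)

    @field_validator("kind")
    @classmethod
    def _known(cls, v):
        if v not in ("classical", "oracle"):
            raise ValueError(f"unknown pose kind {v!r}")
        return v


class LayoutConfig(_Block):
    depths: list[float] = Field(default_factory=lambda: [0.40, 0.50, 0.60, 0.70, 0.80, 0.90])
    n_lateral: int = Field(5, ge=1)
    lateral_extent: float = Field(0.32, ge=0)
    lateral_center: float = 0.049

    @field_validator("depths")
    @classmethod
    def _positive(cls, v):
        if not v or min(v) <= 0:
            raise ValueError("depths must be positive meters")
        return v

    def to_layout(self) -> MeasurementLayout:
        return MeasurementLayout(
            depths=tuple(self.depths), n_lateral=self.n_lateral,
            lateral_extent=self.lateral_extent, lateral_center=self.lateral_center,
        )


class ExperimentConfig(_Block):
    n_frames: int = Field(30, ge=1)
    n_runs: int = Field(1, ge=1)
    outlier_threshold: float = Field(0.10, gt=0, description="meters from median")


class PipelineConfig(_Block):
    """Top-level pipeline configuration; every block has full defaults."""

    seed: int = 0
    rig: RigConfig = Field(default_factory=RigConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    render: RenderConfig = Field(default_factory=RenderConfig)
    detector: DetectorConfig = Field(default_factory=DetectorConfig)
    upscaler: UpscalerConfig = Field(default_factory=UpscalerConfig)
    pose: PoseConfig = Field(default_factory=PoseConfig)
    layout: LayoutConfig = Field(default_factory=LayoutConfig)
    experiment: ExperimentConfig = Field(default_factory=ExperimentConfig)

    def to_experiment_spec(self) -> ExperimentSpec:
        return ExperimentSpec(
            layout=self.layout.to_layout(),
            grid_spec=self.grid.to_spec(),
            rig=self.rig.to_rig(),
            render=self.render.to_settings(seed=self.seed),
            detector=self.detector.kind,
            detector_jitter_px=self.detector.jitter_px,
            pose=self.pose.kind,
            pose_noise_px=self.pose.noise_px,
            upscale_factor=self.upscaler.factor,
            n_frames=self.experiment.n_frames,
            n_runs=self.experiment.n_runs,
            outlier_threshold_m=self.experiment.outlier_threshold,
        )


def validate_config(raw: str | dict | None) -> PipelineConfig:
    """Parse + validate a YAML config; raises :class:`ConfigError` whose
    message names the offending key path."""
    if isinstance(raw, str):
        try:
            data = yaml.safe_load(raw)
        except yaml.YAMLError as exc:
            raise ConfigError(f"config is not valid YAML: {exc}") from None
    else:
        data = raw
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            path = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"{path}: {err['msg']}")
        raise ConfigError("invalid config — " + "; ".join(lines)) from None


def serialize_config(cfg: PipelineConfig) -> str:
    return yaml.safe_dump(cfg.model_dump(), sort_keys=True)


def config_hash(raw: str) -> str:
    return hashlib.sha256(raw.encode()).hexdigest()[:12]
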