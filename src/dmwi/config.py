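"""Validated run configuration.

A run is described by a YAML document with five blocks (geometry, scene,
acquisition, reconstruction, analysis) plus a seed and an output directory.
Unknown keys are rejected so typos fail loudly before any stage runs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from dmwi.dielectrics import WATER_DEBYE, DebyeParameterization
from dmwi.errors import ConfigError
from dmwi.geometry import AntennaArray, ImagingGrid, build_array, build_grid
from dmwi.synthetic import AcquisitionSpec, PhantomScene, air_permittivity


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Block):
    aperture_radius_mm: float = 100.0
    pair_separation_deg: float = 35.0
    pair_offset_deg: float = 90.0
    orientation_deg: float = 107.5
    phase_center_poly: list[float] = Field(default_factory=lambda: [0.0])
    roi_radius_mm: float = 100.0
    pitch_mm: float = 1.0


class SceneConfig(_Block):
    background_temperature_c: float = 25.0
    inclusion_center_mm: tuple[float, float] = (-25.0, 10.0)
    inclusion_radius_mm: float = 4.0
    phantom_inner_radius_mm: float = 105.0
    water_model: str = "stogryn1971"
    inclusion_medium: Literal["water", "air"] = "water"


class AcquisitionConfig(_Block):
    f_start_ghz: float = 0.5
    f_stop_ghz: float = 3.0
    n_points: int = 201
    noise_floor_db: float | None = -100.0
    highband_cutoff_ghz: float = 2.3
    t_start_c: float = 40.5
    t_stop_c: float = 36.0
    t_step_c: float = 0.1
    coupling_scale: float = 0.1
    quadrature_cell_mm: float = 0.25
    timing_noise: bool = True


class ReconstructionConfig(_Block):
    band_low_ghz: float = 0.5
    band_high_ghz: float = 2.0
    conjugate_focusing: bool = False
    channels: list[tuple[int, int]] | None = None  # 1-based pairs; None = all six


class AnalysisConfig(_Block):
    tolerance_mm: float = 9.0
    contrast_band_low_ghz: float = 0.5
    contrast_band_high_ghz: float = 2.0


class RunConfig(_Block):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    scene: SceneConfig = Field(default_factory=SceneConfig)
    acquisition: AcquisitionConfig = Field(default_factory=AcquisitionConfig)
    reconstruction: ReconstructionConfig = Field(default_factory=ReconstructionConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    seed: int = 0
    output_dir: str = "results"

    # -- builders -----------------------------------------------------------

    def water_params(self) -> DebyeParameterization:
        try:
            return WATER_DEBYE[self.scene.water_model]
        except KeyError:
            raise ConfigError(
                f"scene.water_model: unknown parameterization "
                f"{self.scene.water_model!r}; available: {sorted(WATER_DEBYE)}"
            ) from None

    def build_array(self) -> AntennaArray:
        g = self.geometry
        return build_array(
            aperture_radius_mm=g.aperture_radius_mm,
            pair_separation_deg=g.pair_separation_deg,
            pair_offset_deg=g.pair_offset_deg,
            orientation_deg=g.orientation_deg,
            phase_center_poly=np.asarray(g.phase_center_poly, dtype=float),
        )

    def build_grid(self) -> ImagingGrid:
        return build_grid(self.geometry.roi_radius_mm, self.geometry.pitch_mm)

    def build_scene(self, inclusion_temperature_c: float) -> PhantomScene:
        s = self.scene
        return PhantomScene(
            inclusion_temperature_c=inclusion_temperature_c,
            background_temperature_c=s.background_temperature_c,
            inclusion_center_mm=tuple(s.inclusion_center_mm),
            inclusion_radius_mm=s.inclusion_radius_mm,
            phantom_inner_radius_mm=s.phantom_inner_radius_mm,
            params=self.water_params(),
            inclusion_medium=air_permittivity if s.inclusion_medium == "air" else None,
        )

    def build_acquisition(self) -> AcquisitionSpec:
        a = self.acquisition
        return AcquisitionSpec(
            f_start_hz=a.f_start_ghz * 1e9,
            f_stop_hz=a.f_stop_ghz * 1e9,
            n_points=a.n_points,
            noise_floor_db=a.noise_floor_db,
            highband_cutoff_hz=a.highband_cutoff_ghz * 1e9,
            seed=self.seed,
        )

    def channels_zero_based(self) -> tuple[tuple[int, int], ...] | None:
        ch = self.reconstruction.channels
        if ch is None:
            return None
        return tuple((i - 1, j - 1) for (i, j) in ch)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run configuration; defaults when ``path=None``."""
    if path is None:
        return RunConfig()
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"config {path} is not valid YAML: {exc}") from exc
    try:
        return RunConfig.model_validate(raw or {})
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in e["loc"]) + ": " + e["msg"] for e in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: {locs}") from exc
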