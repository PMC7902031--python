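"""YAML run configuration, validated with pydantic before any stage runs.

All numeric field names carry units (``_kpa``, ``_cm``, ``_ug_ml`` ...) so a
config file can never be mis-read in the wrong unit silently.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .dosimetry import NebulizationRun, ParticleSpec
from .geometry import ChamberConfig, MembraneGeometry

__all__ = ["RunConfig", "load_config"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryBlock(_Block):
    radius_a_cm: float = 1.26
    thickness_t_um: float = 5.0
    area_s0_cm2: float | None = None

    def build(self) -> MembraneGeometry:
        return MembraneGeometry(self.radius_a_cm, self.thickness_t_um, self.area_s0_cm2)


class ChamberBlock(_Block):
    ambient_p0_kpa: float = 98.0
    headspace_v0_ml: float = 30.0
    perfusion_rate_ul_min: float = 400.0

    def build(self) -> ChamberConfig:
        return ChamberConfig(self.ambient_p0_kpa, self.headspace_v0_ml, self.perfusion_rate_ul_min)


class ParticleBlock(_Block):
    diameter_nm: float = 100.0
    material_density_g_cm3: float = 1.05

    def build(self) -> ParticleSpec:
        return ParticleSpec(self.diameter_nm, self.material_density_g_cm3)


class NebulizationBlock(_Block):
    nebulized_volume_ul: float = 250.0
    suspension_concentration_mg_ml: float = 1.25
    deposition_factor: float = 0.97
    exposure_area_cm2: float = 146.0

    def build(self) -> NebulizationRun:
        return NebulizationRun(
            self.nebulized_volume_ul,
            self.suspension_concentration_mg_ml,
            self.deposition_factor,
            self.exposure_area_cm2,
        )


class AssayBlock(_Block):
    basal_volume_ml: float = 16.0
    delivered_mass_ug: float = 10.5


class SimulationBlock(_Block):
    duration_s: float = 60.0
    sample_rate_hz: float = 40.0
    target_linear_strain: float = 0.10
    frequency_hz: float = 0.33
    true_modulus_mpa: float = 0.78
    pressure_noise_sd_kpa: float = 0.0


class RunConfig(_Block):
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    chamber: ChamberBlock = Field(default_factory=ChamberBlock)
    particle: ParticleBlock = Field(default_factory=ParticleBlock)
    nebulization: NebulizationBlock = Field(default_factory=NebulizationBlock)
    assay: AssayBlock = Field(default_factory=AssayBlock)
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)
    output_dir: str = "."
    verbosity: int = 1


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run configuration; defaults when *path* is None."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
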