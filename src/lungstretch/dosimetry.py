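"""Aerosol dose accounting for cloud-settling nebulizer exposures.

Nebulized particle suspensions settle onto cell cultures with a known
deposition factor; the bookkeeping here converts run parameters into the two
dose metrics cell-exposure studies report: deposited mass per unit culture
area (μg cm⁻²) and, for monodisperse spheres, the particle surface area
delivered per unit culture area (cm² cm⁻²).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidArgumentError

__all__ = [
    "NebulizationRun",
    "ParticleSpec",
    "deposited_mass_dose",
    "surface_area_dose",
    "civic_delivered_mass",
]

#: Density of polystyrene (g cm⁻³), the standard test-particle material.
RHO_POLYSTYRENE = 1.05


@dataclass(frozen=True)
class NebulizationRun:
    """One cloud-settling exposure run."""

    nebulized_volume_ul: float
    suspension_concentration_mg_ml: float
    deposition_factor: float
    exposure_area_cm2: float

    def __post_init__(self) -> None:
        for name in ("nebulized_volume_ul", "suspension_concentration_mg_ml", "exposure_area_cm2"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 < self.deposition_factor <= 1:
            raise InvalidArgumentError(
                f"deposition_factor must be in (0, 1], got {self.deposition_factor}"
            )


@dataclass(frozen=True)
class ParticleSpec:
    """Monodisperse spherical particle: diameter (nm) and material density (g cm⁻³)."""

    diameter_nm: float
    material_density_g_cm3: float = RHO_POLYSTYRENE

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise InvalidArgumentError(f"diameter_nm must be > 0, got {self.diameter_nm}")
        if self.material_density_g_cm3 <= 0:
            raise InvalidArgumentError(
                f"material_density_g_cm3 must be > 0, got {self.material_density_g_cm3}"
            )

    @property
    def specific_surface_area_cm2_per_ug(self) -> float:
        """Surface area per mass, 6/(ρ·d), for monodisperse spheres."""
        d_cm = self.diameter_nm * 1e-7
        return 6.0 / (self.material_density_g_cm3 * d_cm) * 1e-6  # cm² per μg


def deposited_mass_dose(run: NebulizationRun) -> float:
    """Deposited mass dose (μg cm⁻²): nebulized mass × deposition factor,
    spread over the exposure area."""
    nebulized_ug = run.nebulized_volume_ul * 1e-3 * run.suspension_concentration_mg_ml * 1e3
    return nebulized_ug * run.deposition_factor / run.exposure_area_cm2


def surface_area_dose(mass_dose_ug_cm2: float, particle: ParticleSpec) -> float:
    """Particle surface-area dose (cm² of particle surface per cm² of culture)
    for monodisperse spheres; inversely proportional to diameter at fixed
    mass dose."""
    if mass_dose_ug_cm2 < 0:
        raise InvalidArgumentError(f"mass_dose_ug_cm2 must be >= 0, got {mass_dose_ug_cm2}")
    return mass_dose_ug_cm2 * particle.specific_surface_area_cm2_per_ug


def civic_delivered_mass(
    nebulized_mass_ug: float,
    efficiency: float = 0.52,
    membrane_area_cm2: float = 5.0,
) -> tuple[float, float]:
    """Mass delivered to cells in the stretch bioreactor, whose integrated
    nebulizer deposits a fixed fraction of the nebulized mass onto the
    membrane.  Returns (total delivered μg, dose μg cm⁻²)."""
    if nebulized_mass_ug < 0:
        raise InvalidArgumentError(f"nebulized_mass_ug must be >= 0, got {nebulized_mass_ug}")
    if not 0 < efficiency <= 1:
        raise InvalidArgumentError(f"efficiency must be in (0, 1], got {efficiency}")
    if membrane_area_cm2 <= 0:
        raise InvalidArgumentError(f"membrane_area_cm2 must be > 0, got {membrane_area_cm2}")
    total = nebulized_mass_ug * efficiency
    return total, total / membrane_area_cm2


def round_to_report(mass_dose: float, area_dose: float) -> tuple[float, float]:
    """Doses rounded to conventional reporting precision: mass dose to one
    decimal, surface-area dose to two significant figures."""
    from math import floor, log10

    if area_dose == 0:
        sa = 0.0
    else:
        sa = round(area_dose, -int(floor(log10(abs(area_dose)))) + 1)
    return round(mass_dose, 1), sa
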