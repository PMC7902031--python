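"""Membrane characterisation: porosity estimators and routine assay normalisations.

The membranes are spin-coated blends of poly(ε-caprolactone) (PCL, the
load-bearing phase) and gelatin (a sacrificial phase that dissolves in culture
medium, leaving an interconnected pore network).  Two porosity estimates are
used side by side:

- *empirical*: liquid-displacement gravimetry — the membrane is soaked in
  ethanol and the mass uptake converted to pore volume;
- *theoretical*: the gelatin volume fraction of the blend, an upper limit
  reached when every gelatin island is connected to the surface and dissolves.

The remaining functions are the standard normalisations for WST-1 viability,
LDH release, TEER barrier integrity and proliferation fold used alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import InvalidArgumentError, InvalidMeasurementError

__all__ = [
    "MembraneComposition",
    "GravimetricMeasurement",
    "empirical_porosity",
    "theoretical_porosity",
    "wst1_viability",
    "ldh_release",
    "teer",
    "proliferation_fold",
]

#: Densities (g cm⁻³) of the two blend phases.  Two PCL literature values
#: circulate (1.145 and 1.45); 1.145 is the default because it is the value
#: consistent with the gravimetric analysis and with the reference blend's
#: quoted theoretical porosity.  Pass rho_pcl explicitly to use another.
RHO_PCL_DEFAULT = 1.145
RHO_GELATIN_DEFAULT = 1.30
RHO_ETOH_DEFAULT = 0.789

#: Apparent porosity of a pure-PCL membrane measured by the same gravimetric
#: protocol (ethanol adsorption / intrinsic microporosity); subtracted as a
#: blank from measured porosities.
BLANK_APPARENT_POROSITY_DEFAULT = 0.093


@dataclass(frozen=True)
class MembraneComposition:
    """PCL/gelatin blend, concentrations in % w/v of solvent."""

    c_pcl_pct: float
    c_gelatin_pct: float
    rho_pcl: float = RHO_PCL_DEFAULT
    rho_gelatin: float = RHO_GELATIN_DEFAULT

    def __post_init__(self) -> None:
        if self.c_pcl_pct < 0 or self.c_gelatin_pct < 0:
            raise InvalidArgumentError("polymer concentrations must be non-negative")
        if self.c_pcl_pct == 0 and self.c_gelatin_pct == 0:
            raise InvalidArgumentError("composition cannot be all-zero")
        if self.rho_pcl <= 0 or self.rho_gelatin <= 0:
            raise InvalidArgumentError("densities must be positive")

    def mixture_density(self) -> float:
        """Volume-weighted density of the dry blend (g cm⁻³)."""
        vol = self.c_pcl_pct / self.rho_pcl + self.c_gelatin_pct / self.rho_gelatin
        return (self.c_pcl_pct + self.c_gelatin_pct) / vol


@dataclass(frozen=True)
class GravimetricMeasurement:
    """Dry/ethanol-soaked masses (mg) of one membrane sample."""

    mass_dry_mg: float
    mass_soaked_mg: float
    rho_membrane: float
    rho_etoh: float = RHO_ETOH_DEFAULT
    blank_apparent_porosity: float = BLANK_APPARENT_POROSITY_DEFAULT

    def __post_init__(self) -> None:
        if self.mass_dry_mg <= 0:
            raise InvalidMeasurementError(f"mass_dry_mg must be > 0, got {self.mass_dry_mg}")
        if self.mass_soaked_mg < self.mass_dry_mg:
            raise InvalidMeasurementError(
                f"mass_soaked_mg ({self.mass_soaked_mg}) < mass_dry_mg ({self.mass_dry_mg}); "
                "a soaked sample cannot weigh less than the dry one"
            )
        if self.rho_membrane <= 0 or self.rho_etoh <= 0:
            raise InvalidArgumentError("densities must be positive")
        if self.blank_apparent_porosity < 0:
            raise InvalidArgumentError("blank_apparent_porosity must be non-negative")


def empirical_porosity(g: GravimetricMeasurement) -> float:
    """Liquid-displacement porosity (fraction in [0, 1]).

    Pore volume is the ethanol uptake V_EtOH = (m_soaked − m_dry)/ρ_EtOH,
    solid volume V_m = m_dry/ρ_membrane; raw porosity V_EtOH/(V_EtOH + V_m).
    The blank apparent porosity of a pure-PCL membrane is subtracted; a
    negative corrected value clamps to 0 with a warning (dense membranes can
    fall below the blank).
    """
    v_etoh = (g.mass_soaked_mg - g.mass_dry_mg) / g.rho_etoh
    v_m = g.mass_dry_mg / g.rho_membrane
    raw = v_etoh / (v_etoh + v_m)
    corrected = raw - g.blank_apparent_porosity
    if corrected < 0:
        warnings.warn(
            f"blank correction ({g.blank_apparent_porosity:.3f}) exceeds raw porosity "
            f"({raw:.3f}); clamping to 0",
            stacklevel=2,
        )
        return 0.0
    return corrected


def theoretical_porosity(comp: MembraneComposition) -> float:
    """Upper-limit porosity from the blend composition: the gelatin volume
    fraction (c_gel/ρ_gel) / (c_gel/ρ_gel + c_PCL/ρ_PCL), i.e. the pore space
    left if every gelatin island dissolved.

    The mass amounts per unit solvent volume divided by phase densities give
    phase volumes; their ratio is dimensionless and lies in [0, 1].
    """
    v_gel = comp.c_gelatin_pct / comp.rho_gelatin
    v_pcl = comp.c_pcl_pct / comp.rho_pcl
    return v_gel / (v_gel + v_pcl)


def wst1_viability(abs_sample: float, abs_blank: float, abs_reference: float) -> float:
    """WST-1 metabolic activity as percent of a reference culture, after blank
    subtraction: 100·(A_sample − A_blank)/(A_reference − A_blank)."""
    if abs_reference <= abs_blank:
        raise InvalidArgumentError(
            f"abs_reference ({abs_reference}) must exceed abs_blank ({abs_blank})"
        )
    return 100.0 * (abs_sample - abs_blank) / (abs_reference - abs_blank)


def ldh_release(conc_sample_u_ml: float, vol_sample_ml: float, dose_high_control_u: float) -> float:
    """LDH release as percent of the high control (full lysis) dose.

    LDH dose is concentration × medium volume.  Values below 10% are
    conventionally read as non-cytotoxic.
    """
    if dose_high_control_u <= 0:
        raise InvalidArgumentError(f"dose_high_control_u must be > 0, got {dose_high_control_u}")
    return 100.0 * (conc_sample_u_ml * vol_sample_ml) / dose_high_control_u


def teer(resistance_measured_ohm: float, resistance_blank_ohm: float, area_cm2: float) -> float:
    """Transepithelial electrical resistance in Ω·cm² after subtracting the
    blank (cell-free) membrane resistance.  May be ≤ 0, which flags the
    absence of a functional barrier; no clamping is applied."""
    if area_cm2 <= 0:
        raise InvalidArgumentError(f"area_cm2 must be > 0, got {area_cm2}")
    return (resistance_measured_ohm - resistance_blank_ohm) * area_cm2


def proliferation_fold(final_density_cells_cm2: float, seeding_density_cells_cm2: float) -> float:
    """Cell-number fold increase over the seeding density, reported to one
    decimal place as conventional for proliferation figures."""
    if final_density_cells_cm2 <= 0 or seeding_density_cells_cm2 <= 0:
        raise InvalidArgumentError("cell densities must be positive")
    return round(final_density_cells_cm2 / seeding_density_cells_cm2, 1)
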