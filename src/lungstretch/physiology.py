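"""Breathing physiology ↔ membrane strain mapping.

Bench stretch amplitudes are chosen to mimic breathing.  Treating the
alveolar sacs as spheres, a tidal volume V_T on top of the functional
residual capacity (FRC) inflates the lung by a fraction f = V_T/FRC, and the
alveolar walls experience

    linear strain  ε  = (1 + f)^(1/3) − 1
    area strain        = (1 + f)^(2/3) − 1

with the exact sphere identity (1 + ε)² − 1 = area strain.  The inverse maps
a chosen membrane strain back to the tidal volume it emulates.  Reference
breathing patterns (ICRP population averages for light/heavy exercise, male
and female) are bundled for convenience.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import InvalidArgumentError

__all__ = [
    "BreathingPattern",
    "StrainRegime",
    "ICRP_PATTERNS",
    "volume_expansion",
    "strain_from_volume_expansion",
    "tidal_volume_from_linear_strain",
    "classify_strain",
    "area_perfusion_ratio",
]


@dataclass(frozen=True)
class BreathingPattern:
    """Tidal volume (L), functional residual capacity (L), breathing rate (min⁻¹)."""

    tidal_volume_l: float
    frc_l: float
    frequency_bpm: float

    def __post_init__(self) -> None:
        if self.tidal_volume_l <= 0 or self.frc_l <= 0 or self.frequency_bpm <= 0:
            raise InvalidArgumentError("tidal volume, FRC and frequency must all be positive")


#: ICRP population-average breathing patterns with representative FRC values.
ICRP_PATTERNS: dict[str, BreathingPattern] = {
    "heavy_exercise_male": BreathingPattern(1.92, 3.3, 26),
    "heavy_exercise_female": BreathingPattern(1.36, 2.7, 33),
    "light_exercise_male": BreathingPattern(1.25, 3.3, 20),
    "light_exercise_female": BreathingPattern(0.99, 2.7, 21),
}


class StrainRegime(enum.Enum):
    PHYSIOLOGIC = "physiologic"
    OVERSTRETCH = "overstretch"
    BEYOND_MEMBRANE_LIMIT = "beyond_membrane_limit"


def volume_expansion(pattern: BreathingPattern) -> float:
    """Fractional lung-volume increase over FRC: tidal volume / FRC."""
    return pattern.tidal_volume_l / pattern.frc_l


def strain_from_volume_expansion(expansion_fraction: float) -> tuple[float, float]:
    """(linear, area) strain of a spherical alveolus inflated by the given
    volume fraction: ((1+f)^(1/3) − 1, (1+f)^(2/3) − 1)."""
    if expansion_fraction < 0:
        raise InvalidArgumentError(
            f"expansion_fraction must be >= 0, got {expansion_fraction}"
        )
    linear = (1.0 + expansion_fraction) ** (1.0 / 3.0) - 1.0
    area = (1.0 + expansion_fraction) ** (2.0 / 3.0) - 1.0
    return linear, area


def tidal_volume_from_linear_strain(linear_strain: float, frc_l: float) -> float:
    """Tidal volume (L) producing the given alveolar linear strain at the
    given FRC: ((1+ε)³ − 1)·FRC — the exact inverse of
    :func:`strain_from_volume_expansion`."""
    if linear_strain < 0:
        raise InvalidArgumentError(f"linear_strain must be >= 0, got {linear_strain}")
    if frc_l <= 0:
        raise InvalidArgumentError(f"frc_l must be > 0, got {frc_l}")
    return ((1.0 + linear_strain) ** 3 - 1.0) * frc_l


def classify_strain(
    linear_strain: float,
    *,
    overstretch_threshold: float = 0.17,
    membrane_limit_threshold: float = 0.25,
) -> StrainRegime:
    """Strain regime: physiologic up to 17% linear, over-stretch up to the 25%
    reversible-strain tolerance of the membrane, beyond-limit above that."""
    if linear_strain < 0:
        raise InvalidArgumentError(f"linear_strain must be >= 0, got {linear_strain}")
    if linear_strain <= overstretch_threshold:
        return StrainRegime.PHYSIOLOGIC
    if linear_strain <= membrane_limit_threshold:
        return StrainRegime.OVERSTRETCH
    return StrainRegime.BEYOND_MEMBRANE_LIMIT


def area_perfusion_ratio(area_cm2: float, flow_ul_min: float) -> float:
    """Exchange-area to perfusion-rate ratio in m² per (L min⁻¹) — the metric
    comparing a bioreactor's membrane/perfusion balance to the lung's
    (≈ 20 m² per L min⁻¹ at rest)."""
    if area_cm2 <= 0 or flow_ul_min <= 0:
        raise InvalidArgumentError("area and flow must both be positive")
    return (area_cm2 * 1e-4) / (flow_ul_min * 1e-6)
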