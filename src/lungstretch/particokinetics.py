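"""Particle translocation and cellular-uptake quantification.

Transepithelial translocation is measured by fluorescence spectroscopy of the
basal culture medium: a standard curve of the particle suspension converts
the basal reading into a concentration, and the recovered particle mass is
expressed as a percentage of the cell-delivered dose.  Readings that cannot
be distinguished from blank medium are reported as below the limit of
detection (LOD, mean blank + 3 SD) together with the LOD expressed as a
fraction — never as zero.

Cellular uptake is quantified from background-subtracted mean fluorescence
intensities of confocal z-stack fields, summarised per condition and compared
as a fold change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateCurveError, InvalidArgumentError

__all__ = [
    "StandardCurve",
    "TranslocationResult",
    "FieldIntensitySummary",
    "fit_standard_curve",
    "translocated_fraction",
    "uptake_intensity",
    "uptake_fold_change",
]


@dataclass(frozen=True)
class StandardCurve:
    """Linear fluorescence-vs-concentration calibration."""

    slope_au_per_ug_ml: float
    intercept_au: float
    residual_sd_au: float
    lod_concentration_ug_ml: float

    def concentration(self, fluorescence_au: float) -> float:
        """Invert the curve: concentration (μg mL⁻¹) for a reading (AU)."""
        return (fluorescence_au - self.intercept_au) / self.slope_au_per_ug_ml


@dataclass(frozen=True)
class TranslocationResult:
    """Translocated fraction (% of delivered dose) with LOD bookkeeping."""

    fraction_percent: float
    below_lod: bool
    lod_fraction_percent: float

    def __str__(self) -> str:
        if self.below_lod:
            return f"<LOD ({self.lod_fraction_percent:.1f}%)"
        return f"{self.fraction_percent:.1f}%"


@dataclass(frozen=True)
class FieldIntensitySummary:
    """Background-subtracted mean intensities of independent imaging fields."""

    field_intensities_au: tuple[float, ...]
    region_um: tuple[float, float] = (134.95, 134.95)

    def __post_init__(self) -> None:
        if len(self.field_intensities_au) < 1:
            raise InvalidArgumentError("at least one field is required")
        object.__setattr__(self, "field_intensities_au", tuple(self.field_intensities_au))

    @property
    def field_count(self) -> int:
        return len(self.field_intensities_au)


def fit_standard_curve(
    concentrations_ug_ml: Sequence[float],
    fluorescence_au: Sequence[float],
    blanks_au: Sequence[float],
    *,
    through_origin: bool = False,
) -> StandardCurve:
    """Ordinary least-squares standard curve with a blank-based LOD.

    The LOD concentration is the spectroscopy convention
    (mean(blanks) + 3·SD(blanks) − intercept)/slope, floored at 0.  The curve
    is fitted with a free intercept by default because culture medium
    autofluoresces; ``through_origin`` forces the intercept to 0.
    """
    conc = np.asarray(concentrations_ug_ml, dtype=float)
    fluo = np.asarray(fluorescence_au, dtype=float)
    blanks = np.asarray(blanks_au, dtype=float)
    if conc.size < 3 or np.unique(conc).size < 3:
        raise InvalidArgumentError("at least 3 distinct concentration levels are required")
    if conc.size != fluo.size:
        raise InvalidArgumentError("concentrations and fluorescence must have equal length")
    if blanks.size < 3:
        raise InvalidArgumentError("at least 3 blank readings are required")

    if through_origin:
        slope = float(conc @ fluo / (conc @ conc))
        intercept = 0.0
        resid = fluo - slope * conc
        dof = max(conc.size - 1, 1)
    else:
        fit = stats.linregress(conc, fluo)
        slope, intercept = float(fit.slope), float(fit.intercept)
        resid = fluo - (slope * conc + intercept)
        dof = max(conc.size - 2, 1)
    if slope <= 0:
        raise DegenerateCurveError(
            f"fitted slope {slope:.4g} is not positive; the curve cannot be inverted"
        )
    residual_sd = float(np.sqrt((resid @ resid) / dof))
    lod = (float(blanks.mean()) + 3.0 * float(blanks.std(ddof=1)) - intercept) / slope
    return StandardCurve(slope, intercept, residual_sd, max(lod, 0.0))


def translocated_fraction(
    basal_fluorescence_au: float,
    curve: StandardCurve,
    basal_volume_ml: float,
    delivered_mass_ug: float,
) -> TranslocationResult:
    """Translocated fraction of the delivered dose recovered in the basal medium.

    concentration = (F − intercept)/slope; fraction = 100·c·V_basal/m_delivered.
    Readings at or below blank level, or below the LOD concentration, are
    flagged ``below_lod`` and carry the LOD-equivalent fraction as an upper
    bound.
    """
    if delivered_mass_ug <= 0:
        raise InvalidArgumentError(f"delivered_mass_ug must be > 0, got {delivered_mass_ug}")
    if basal_volume_ml <= 0:
        raise InvalidArgumentError(f"basal_volume_ml must be > 0, got {basal_volume_ml}")
    conc = curve.concentration(basal_fluorescence_au)
    to_fraction = 100.0 * basal_volume_ml / delivered_mass_ug
    lod_fraction = curve.lod_concentration_ug_ml * to_fraction
    below = conc <= 0.0 or conc < curve.lod_concentration_ug_ml
    fraction = max(conc, 0.0) * to_fraction
    return TranslocationResult(fraction, below, lod_fraction)


def uptake_intensity(stack_fields: FieldIntensitySummary) -> tuple[float, float]:
    """Mean and SD over fields of the background-subtracted mean intensities
    (AU).  SD is 0 for a single field."""
    vals = np.asarray(stack_fields.field_intensities_au, dtype=float)
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd


def uptake_fold_change(condition_a_au: float, condition_b_au: float) -> float:
    """Fold change of mean uptake intensity between two conditions (a/b),
    reported to one decimal place."""
    if condition_b_au <= 0:
        raise InvalidArgumentError(f"condition_b_au must be > 0, got {condition_b_au}")
    if condition_a_au < 0:
        raise InvalidArgumentError(f"condition_a_au must be >= 0, got {condition_a_au}")
    return round(condition_a_au / condition_b_au, 1)
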