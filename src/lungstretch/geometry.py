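"""Domain types and spherical-cap deflection geometry.

A circular elastic membrane of radius ``a`` clamped at its rim and inflated by
a positive apical pressure bulges into a spherical cap of apex height ``Δh``.
The cap volume, the apex height recovered from a measured volume, and the
linear/area strain of the membrane surface are the geometric primitives every
other stage of the pipeline builds on.

Unit conventions follow bench practice for this class of bioreactor: lengths
in cm (membrane thickness in μm), volumes in mL (≡ cm³), pressures in kPa,
perfusion in μL min⁻¹.  These units are mutually consistent for all formulas
in this package, so no hidden conversion layer is needed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidArgumentError

__all__ = [
    "MembraneGeometry",
    "ChamberConfig",
    "DeflectionState",
    "cap_volume",
    "cap_height_from_volume",
    "strain_from_height",
]

#: Apex heights above this fraction of the radius are outside the small-cap
#: regime the monitoring electronics were validated in; states are computed
#: anyway but flagged by higher-level code.
SMALL_CAP_LIMIT_FRACTION = 0.11 / 1.26


@dataclass(frozen=True)
class MembraneGeometry:
    """Circular elastic membrane: radius (cm), thickness (μm), reference area (cm²).

    ``area_s0_cm2`` defaults to ``π a²`` and, when given explicitly, must agree
    with it to 0.5% unless ``allow_area_mismatch`` is set (some holders mask
    part of the membrane).
    """

    radius_a_cm: float = 1.26
    thickness_t_um: float = 5.0
    area_s0_cm2: float | None = None
    allow_area_mismatch: bool = False

    def __post_init__(self) -> None:
        if self.radius_a_cm <= 0:
            raise InvalidArgumentError(f"radius_a_cm must be > 0, got {self.radius_a_cm}")
        if self.thickness_t_um <= 0:
            raise InvalidArgumentError(f"thickness_t_um must be > 0, got {self.thickness_t_um}")
        circle = math.pi * self.radius_a_cm**2
        if self.area_s0_cm2 is None:
            object.__setattr__(self, "area_s0_cm2", circle)
        elif not self.allow_area_mismatch and abs(self.area_s0_cm2 - circle) > 0.005 * circle:
            raise InvalidArgumentError(
                f"area_s0_cm2={self.area_s0_cm2} differs from pi*a^2={circle:.4f} by more "
                "than 0.5%; pass allow_area_mismatch=True to override"
            )

    @property
    def thickness_t_cm(self) -> float:
        return self.thickness_t_um * 1e-4


@dataclass(frozen=True)
class ChamberConfig:
    """Sealed two-compartment chamber: ambient pressure (kPa), reservoir
    headspace volume (mL), basal perfusion rate (μL min⁻¹)."""

    ambient_p0_kpa: float = 98.0
    headspace_v0_ml: float = 30.0
    perfusion_rate_ul_min: float = 400.0

    def __post_init__(self) -> None:
        if self.ambient_p0_kpa <= 0:
            raise InvalidArgumentError(f"ambient_p0_kpa must be > 0, got {self.ambient_p0_kpa}")
        if self.headspace_v0_ml <= 0:
            raise InvalidArgumentError(f"headspace_v0_ml must be > 0, got {self.headspace_v0_ml}")


@dataclass(frozen=True)
class DeflectionState:
    """Instantaneous derived quantities for one membrane state.

    ``delta_p_kpa`` is the reservoir overpressure P2 − P0; ``delta_p_prime_kpa``
    is the transmembrane pressure P1 − P2 that loads the membrane itself.
    """

    delta_h_cm: float
    delta_v_ml: float
    delta_p_kpa: float
    delta_p_prime_kpa: float
    linear_strain: float
    area_strain: float

    def __post_init__(self) -> None:
        if self.delta_h_cm < 0 or self.delta_v_ml < 0:
            raise InvalidArgumentError("delta_h_cm and delta_v_ml must be non-negative")


def cap_volume(delta_h_cm, radius_a_cm: float):
    """Volume (mL) of a spherical cap of apex height ``Δh`` on a circular base
    of radius ``a``:  V = π·Δh·(a²/2 + Δh²/6).

    Accepts a scalar or array ``delta_h_cm``.  Strictly increasing in Δh; at
    Δh = a it equals the hemisphere volume 2πa³/3.
    """
    if radius_a_cm <= 0:
        raise InvalidArgumentError(f"radius_a_cm must be > 0, got {radius_a_cm}")
    h = np.asarray(delta_h_cm, dtype=float)
    if np.any(h < 0):
        raise InvalidArgumentError("delta_h_cm must be non-negative")
    v = np.pi * h * (radius_a_cm**2 / 2.0 + h**2 / 6.0)
    return float(v) if np.ndim(delta_h_cm) == 0 else v


def _cap_height_closed_form(delta_v_ml, radius_a_cm: float):
    """Vectorised unique non-negative root of (π/6)h³ + (πa²/2)h − V = 0.

    Cardano's formula for the depressed cubic h³ + 3a²h − 6V/π = 0, followed by
    one Newton step to polish the residual to machine precision.
    """
    v = np.asarray(delta_v_ml, dtype=float)
    p = 3.0 * radius_a_cm**2
    q = -6.0 * v / np.pi
    disc = np.sqrt((q / 2.0) ** 2 + (p / 3.0) ** 3)
    h = np.cbrt(-q / 2.0 + disc) + np.cbrt(-q / 2.0 - disc)
    h = np.maximum(h, 0.0)
    # Newton polish on f(h) = π h (a²/2 + h²/6) − V
    f = np.pi * h * (radius_a_cm**2 / 2.0 + h**2 / 6.0) - v
    fp = np.pi * (radius_a_cm**2 / 2.0 + h**2 / 2.0)
    h = np.maximum(h - f / fp, 0.0)
    return h


def cap_height_from_volume(delta_v_ml: float, radius_a_cm: float) -> float:
    """Apex height Δh (cm) of the spherical cap enclosing volume ``delta_V``.

    Solves the monotone cubic by bracketed root-finding on [0, 10a]; the
    round trip through :func:`cap_volume` holds to 1e−9 relative tolerance.
    """
    if radius_a_cm <= 0:
        raise InvalidArgumentError(f"radius_a_cm must be > 0, got {radius_a_cm}")
    if delta_v_ml < 0:
        raise InvalidArgumentError(f"delta_v_ml must be non-negative, got {delta_v_ml}")
    if delta_v_ml == 0:
        return 0.0
    hi = 10.0 * radius_a_cm
    if cap_volume(hi, radius_a_cm) < delta_v_ml:
        raise InvalidArgumentError(
            f"delta_v_ml={delta_v_ml} exceeds the cap volume at h=10a; not a physical state"
        )
    return float(
        brentq(lambda h: cap_volume(h, radius_a_cm) - delta_v_ml, 0.0, hi, xtol=1e-14, rtol=1e-15)
    )


AreaStrainConvention = Literal["text", "eq_printed"]


def strain_from_height(
    delta_h_cm,
    radius_a_cm: float,
    convention: AreaStrainConvention = "text",
):
    """Linear and area strain of the bulged membrane.

    Linear strain is always ``Δh/a``.  Two area-strain conventions circulate
    for the spherical-cap bulge test:

    - ``"text"`` (default): ΔS/S = (1 + Δh/a)² − 1, the fractional area change
      of a surface whose linear dimension stretched by Δh/a.  This is the
      convention all worked stretch figures in this setup follow (10% linear ↔
      21% area).
    - ``"eq_printed"``: ΔS/S = (Δh/a)², the small-deflection form sometimes
      printed alongside the cap formulas; kept for fidelity.
    """
    if radius_a_cm <= 0:
        raise InvalidArgumentError(f"radius_a_cm must be > 0, got {radius_a_cm}")
    h = np.asarray(delta_h_cm, dtype=float)
    if np.any(h < 0):
        raise InvalidArgumentError("delta_h_cm must be non-negative")
    if np.any(h > radius_a_cm):
        warnings.warn(
            "delta_h exceeds the membrane radius; strain values are extrapolated",
            stacklevel=2,
        )
    linear = h / radius_a_cm
    if convention == "text":
        area = (1.0 + linear) ** 2 - 1.0
    elif convention == "eq_printed":
        area = linear**2
    else:
        raise InvalidArgumentError(
            f"unknown area-strain convention {convention!r}; use 'text' or 'eq_printed'"
        )
    if np.ndim(delta_h_cm) == 0:
        return float(linear), float(area)
    return linear, area
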