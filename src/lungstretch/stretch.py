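"""Pressure-based stretch monitoring: from dual pressure signals to strain,
frequency and the membrane's triaxial Young's modulus.

The bioreactor stretches a cell-covered membrane by cyclic positive pressure
on the apical side.  Two sensors are read continuously: P1 in the apical
compartment and P2 in the sealed air headspace of the medium reservoir.
Because the medium is incompressible, the dome volume ΔV swept by the bulging
membrane compresses the reservoir headspace, so P2 encodes ΔV (ideal-gas
bookkeeping), ΔV encodes the apex height Δh (spherical-cap geometry), and the
transmembrane pressure ΔP′ = P1 − P2 together with Δh encodes the Young's
modulus E through the bulge-test relation

    ΔP′ = 4·E·(Δh/a)·t / (3·a·((Δh/a)² + 1)) · (1 − 1/(1 + (Δh/a)²)³)

with membrane radius a and thickness t.  ΔP′ is linear in E, so the modulus
inversion is a division by a purely geometric coefficient.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import InsufficientCyclesError, InvalidArgumentError, SingularStateError
from .geometry import (
    ChamberConfig,
    MembraneGeometry,
    _cap_height_closed_form,
    strain_from_height,
)

__all__ = [
    "PressureTrace",
    "StretchReport",
    "volume_from_reservoir_pressure",
    "transmembrane_pressure_from_modulus",
    "modulus_from_state",
    "pressure_modulus_coefficient",
    "analyze_trace",
]

TRACE_COLUMNS = ["time_s", "p1_kpa", "p2_kpa"]
SAMPLE_COLUMNS = [
    "time_s",
    "delta_v_ml",
    "delta_h_cm",
    "linear_strain",
    "area_strain",
    "dp_prime_kpa",
]


@dataclass(frozen=True)
class PressureTrace:
    """Timestamped apical (P1) and reservoir-headspace (P2) pressures in kPa."""

    time_s: np.ndarray
    p1_kpa: np.ndarray
    p2_kpa: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        p1 = np.asarray(self.p1_kpa, dtype=float)
        p2 = np.asarray(self.p2_kpa, dtype=float)
        if not (t.shape == p1.shape == p2.shape) or t.ndim != 1:
            raise InvalidArgumentError("time_s, p1_kpa, p2_kpa must be 1-D arrays of equal length")
        if t.size < 2:
            raise InvalidArgumentError("a pressure trace needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("time_s must be strictly increasing")
        if np.any(p1 <= 0) or np.any(p2 <= 0):
            raise InvalidArgumentError("pressures must be strictly positive (absolute kPa)")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "p1_kpa", p1)
        object.__setattr__(self, "p2_kpa", p2)

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    @classmethod
    def from_csv(cls, path: str | Path) -> "PressureTrace":
        df = pd.read_csv(path)
        missing = [c for c in TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise InvalidArgumentError(
                f"trace CSV {path} is missing required column(s): {', '.join(missing)}"
            )
        return cls(df["time_s"].to_numpy(), df["p1_kpa"].to_numpy(), df["p2_kpa"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_s": self.time_s, "p1_kpa": self.p1_kpa, "p2_kpa": self.p2_kpa}
        ).to_csv(path, index=False)


@dataclass
class StretchReport:
    """Cycle-resolved stretch summary for one monitored run."""

    frequency_hz: float
    cycle_count: int
    per_cycle: pd.DataFrame  # peak_linear_strain, modulus_mpa, over_stretch, beyond_membrane_limit
    samples: pd.DataFrame  # SAMPLE_COLUMNS (+ clamped flag)
    strain_mean: float = 0.0
    strain_sd: float = 0.0
    modulus_mean_mpa: float = float("nan")
    modulus_sd_mpa: float = float("nan")

    def summary_dict(self) -> dict:
        return {
            "frequency_hz": self.frequency_hz,
            "cycle_count": self.cycle_count,
            "peak_linear_strain_mean": self.strain_mean,
            "peak_linear_strain_sd": self.strain_sd,
            "modulus_mean_mpa": self.modulus_mean_mpa,
            "modulus_sd_mpa": self.modulus_sd_mpa,
            "over_stretch_cycles": int(self.per_cycle["over_stretch"].sum()),
            "beyond_membrane_limit_cycles": int(self.per_cycle["beyond_membrane_limit"].sum()),
        }

    def to_json(self, path: str | Path) -> None:
        payload = self.summary_dict()
        payload["per_cycle"] = self.per_cycle.to_dict(orient="list")
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, allow_nan=True))


def volume_from_reservoir_pressure(
    p2_kpa,
    config: ChamberConfig,
    mode: Literal["linearized", "isothermal"] = "linearized",
):
    """Dome volume ΔV (mL) inferred from the reservoir headspace pressure P2.

    ``"linearized"`` (default) is the first-order ideal-gas bookkeeping
    ΔV = (P2 − P0)·V0/P0; ``"isothermal"`` is the exact Boyle form
    ΔV = V0·(1 − P0/P2).  The two agree to first order in ΔP/P0.

    P2 below ambient (sensor drift) is clamped to ΔV = 0 with a warning.
    Accepts scalars or arrays.
    """
    p2 = np.asarray(p2_kpa, dtype=float)
    if np.any(p2 <= 0):
        raise InvalidArgumentError("p2_kpa must be strictly positive (absolute kPa)")
    p0, v0 = config.ambient_p0_kpa, config.headspace_v0_ml
    if np.any(p2 < p0):
        warnings.warn(
            "P2 below ambient pressure encountered; clamping the implied volume to 0",
            stacklevel=2,
        )
    if mode == "linearized":
        dv = (p2 - p0) * v0 / p0
    elif mode == "isothermal":
        dv = v0 * (1.0 - p0 / p2)
    else:
        raise InvalidArgumentError(f"unknown mode {mode!r}; use 'linearized' or 'isothermal'")
    dv = np.maximum(dv, 0.0)
    return float(dv) if np.ndim(p2_kpa) == 0 else dv


def pressure_modulus_coefficient(delta_h_cm, geometry: MembraneGeometry):
    """Geometric coefficient k(Δh) (kPa per MPa) of the bulge-test relation,
    so that ΔP′ = k(Δh)·E with E in MPa.  Vanishes at Δh = 0."""
    h = np.asarray(delta_h_cm, dtype=float)
    if np.any(h < 0):
        raise InvalidArgumentError("delta_h_cm must be non-negative")
    a = geometry.radius_a_cm
    t = geometry.thickness_t_cm
    x = h / a
    x2 = x * x
    k = 1000.0 * (4.0 * x * t) / (3.0 * a * (x2 + 1.0)) * (1.0 - 1.0 / (1.0 + x2) ** 3)
    return float(k) if np.ndim(delta_h_cm) == 0 else k


def transmembrane_pressure_from_modulus(
    delta_h_cm: float, modulus_e_mpa: float, geometry: MembraneGeometry
) -> float:
    """Transmembrane pressure ΔP′ = P1 − P2 (kPa) predicted by the bulge-test
    relation at apex height ``delta_h_cm`` for a membrane of modulus E (MPa)."""
    if modulus_e_mpa <= 0:
        raise InvalidArgumentError(f"modulus_e_mpa must be > 0, got {modulus_e_mpa}")
    return pressure_modulus_coefficient(delta_h_cm, geometry) * modulus_e_mpa


def modulus_from_state(
    delta_p_prime_kpa: float, delta_h_cm: float, geometry: MembraneGeometry
) -> float:
    """Young's modulus E (MPa) from one (ΔP′, Δh) state — the bulge-test
    inversion.  Unidentifiable at Δh = 0."""
    if delta_h_cm <= 0:
        raise SingularStateError("modulus is unidentifiable at zero deflection (delta_h_cm <= 0)")
    if delta_p_prime_kpa <= 0:
        raise InvalidArgumentError(
            f"delta_p_prime_kpa must be > 0, got {delta_p_prime_kpa}"
        )
    return delta_p_prime_kpa / pressure_modulus_coefficient(delta_h_cm, geometry)


def _dominant_period_samples(x: np.ndarray) -> int | None:
    """Dominant oscillation period (in samples) from the autocorrelation
    maximum beyond its first zero crossing; None if no oscillation is found."""
    x = x - x.mean()
    if np.ptp(x) == 0:
        return None
    ac = np.correlate(x, x, mode="full")[x.size - 1 :]
    below = np.nonzero(ac < 0)[0]
    if below.size == 0:
        return None
    start = below[0]
    if start >= ac.size - 1:
        return None
    lag = start + int(np.argmax(ac[start:]))
    return lag if lag > 0 else None


def _fit_peak_strain(t: np.ndarray, y: np.ndarray, omega: float, fallback: float) -> float:
    """Cycle-peak strain from a single-harmonic least-squares fit.

    Fits y(t) = b0 + b1 cos(ωt) + b2 sin(ωt) over one cycle window and returns
    b0 + sqrt(b1² + b2²), the waveform maximum.  Exact for any sinusoidal
    actuation (raised-cosine or offset sinusoid) independent of how the
    sampling grid falls, and linear in the data, so sensor noise does not bias
    it.  Falls back to the raw window maximum for degenerate windows.
    """
    if t.size < 5:
        return fallback
    design = np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    b0, b1, b2 = coef
    return float(b0 + np.hypot(b1, b2))


def analyze_trace(
    trace: PressureTrace,
    geometry: MembraneGeometry,
    config: ChamberConfig,
    *,
    volume_mode: Literal["linearized", "isothermal"] = "linearized",
    area_strain_convention: str = "text",
    overstretch_threshold: float = 0.17,
    membrane_limit_threshold: float = 0.25,
    modulus_estimator: Literal["peak", "plateau"] = "peak",
) -> StretchReport:
    """Full monitoring pass over a dual-pressure trace.

    Per sample: ΔV from P2 (clamped to 0 below ambient and flagged), Δh by
    inverting the cap volume, linear/area strain, and ΔP′ = P1 − P2.  Cycles
    are located as local maxima of mean-subtracted P2 with prominence ≥ 25% of
    the peak-to-trough range and minimum separation 0.4× the dominant period
    (autocorrelation estimate); frequency is 1/median(peak spacing).  Each
    cycle's modulus comes from the bulge-test inversion at its maximum-Δh
    sample (``"peak"``), or averaged over samples above 50% of the cycle peak
    (``"plateau"``).  Cycles whose peak linear strain exceeds
    ``overstretch_threshold`` are flagged as over-stretch and those beyond
    ``membrane_limit_threshold`` as exceeding the membrane's strain tolerance.

    Raises :class:`InsufficientCyclesError` (carrying the per-sample table)
    when fewer than two cycles are detected.
    """
    p2 = trace.p2_kpa
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dv = volume_from_reservoir_pressure(p2, config, mode=volume_mode)
    clamped = p2 < config.ambient_p0_kpa
    dh = _cap_height_closed_form(dv, geometry.radius_a_cm)
    linear, area = strain_from_height(dh, geometry.radius_a_cm, area_strain_convention)
    dp_prime = trace.p1_kpa - p2

    samples = pd.DataFrame(
        {
            "time_s": trace.time_s,
            "delta_v_ml": dv,
            "delta_h_cm": dh,
            "linear_strain": linear,
            "area_strain": area,
            "dp_prime_kpa": dp_prime,
            "clamped": clamped,
        }
    )

    x = p2 - p2.mean()
    period = _dominant_period_samples(x)
    peaks = np.array([], dtype=int)
    if period is not None and np.ptp(x) > 0:
        distance = max(1, int(round(0.4 * period)))
        peaks, _ = find_peaks(x, prominence=0.25 * np.ptp(x), distance=distance)
    if peaks.size < 2:
        raise InsufficientCyclesError(
            f"detected {peaks.size} stretch cycle(s); at least 2 are required "
            "for frequency estimation",
            samples=samples,
        )

    peak_times = trace.time_s[peaks]
    period_s = float(np.median(np.diff(peak_times)))
    frequency = 1.0 / period_s
    omega = 2.0 * np.pi * frequency

    # Anchor each cycle on a regular grid t0 + k*T fitted to all detected peak
    # times.  Individual detected peaks jitter with the sensor noise at their
    # own sample; anchoring estimation windows on the pooled grid (each peak
    # contributes only 1/n to the grid offset) keeps the window contents
    # statistically independent of any single noise draw, which matters
    # because the transmembrane pressure signal can sit far below the noise.
    ks = np.arange(peaks.size)
    t0 = float(np.mean(peak_times - ks * period_s))
    grid_times = t0 + ks * period_s
    anchors = np.searchsorted(trace.time_s, grid_times)
    anchors = np.clip(anchors, 0, len(trace) - 1)
    bounds = np.concatenate(([0], (anchors[:-1] + anchors[1:]) // 2 + 1, [len(trace)]))

    # internal signed deflection: the odd extension of the cap inversion keeps
    # the sensor noise zero-mean through the nonlinearity instead of folding it
    # at zero the way the clamped per-sample output does
    dv_signed = (p2 - config.ambient_p0_kpa) * config.headspace_v0_ml / config.ambient_p0_kpa
    dh_signed = np.sign(dv_signed) * _cap_height_closed_form(np.abs(dv_signed), geometry.radius_a_cm)
    linear_signed = dh_signed / geometry.radius_a_cm

    k_all = pressure_modulus_coefficient(dh, geometry)
    half_w = max(2, int(round(period / 8)))
    records = []
    for i in range(anchors.size):
        lo, hi = bounds[i], bounds[i + 1]
        p = int(anchors[i])
        win = np.arange(max(lo, p - half_w), min(hi, p + half_w + 1))
        cyc = np.arange(lo, hi)
        peak_strain = _fit_peak_strain(
            trace.time_s[cyc], linear_signed[cyc], omega, float(np.max(linear[cyc]))
        )
        if modulus_estimator == "peak":
            # ratio of near-peak window sums: exactly E when dp' = k*E
            # pointwise, and the zero-mean sensor noise in dp' averages out
            ksum = float(k_all[win].sum())
            e = float(dp_prime[win].sum() / ksum) if ksum > 0 else float("nan")
        elif modulus_estimator == "plateau":
            sel = cyc[dh[cyc] > 0.5 * dh[cyc].max()]
            sel = sel[k_all[sel] > 0]
            e = float(np.mean(dp_prime[sel] / k_all[sel])) if sel.size else float("nan")
        else:
            raise InvalidArgumentError(
                f"unknown modulus_estimator {modulus_estimator!r}; use 'peak' or 'plateau'"
            )
        records.append(
            {
                "cycle": i,
                "peak_time_s": float(trace.time_s[p]),
                "peak_linear_strain": peak_strain,
                "modulus_mpa": e,
                "over_stretch": peak_strain > overstretch_threshold,
                "beyond_membrane_limit": peak_strain > membrane_limit_threshold,
            }
        )
    per_cycle = pd.DataFrame.from_records(records)

    e_vals = per_cycle["modulus_mpa"].to_numpy()
    e_vals = e_vals[np.isfinite(e_vals)]
    return StretchReport(
        frequency_hz=frequency,
        cycle_count=int(peaks.size),
        per_cycle=per_cycle,
        samples=samples,
        strain_mean=float(per_cycle["peak_linear_strain"].mean()),
        strain_sd=float(per_cycle["peak_linear_strain"].std(ddof=1)),
        modulus_mean_mpa=float(e_vals.mean()) if e_vals.size else float("nan"),
        modulus_sd_mpa=float(e_vals.std(ddof=1)) if e_vals.size > 1 else float("nan"),
    )
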