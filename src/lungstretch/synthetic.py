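"""Synthetic instrument-like data with the statistical structure the analysis
assumes.

Each generator is the exact forward model of its paired analysis stage, so
noiseless closed loops are exact and noisy closed loops are unbiased within
Monte-Carlo error:

- pressure traces: a raised-cosine stretch waveform (membrane returns to flat
  each cycle, matching positive-pressure actuation from a relaxed state) is
  pushed through the cap-volume, gas-bookkeeping and bulge-test relations to
  produce P1/P2 channels with additive Gaussian sensor noise;
- fluorescence experiments: plate-reader readings linear in concentration
  with Gaussian noise and a blank population;
- gravimetric series: dry/soaked masses with weighing noise;
- intensity stacks: per-field imaging means with Gaussian field-to-field
  scatter.

A single global seed fans out into named substreams, so adding one generator
call does not perturb the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .errors import AliasingError, InvalidArgumentError
from .geometry import ChamberConfig, MembraneGeometry, cap_volume
from .membrane import GravimetricMeasurement
from .particokinetics import FieldIntensitySummary
from .stretch import PressureTrace, pressure_modulus_coefficient

__all__ = [
    "PressureTraceSpec",
    "FluorescenceSpec",
    "GravimetricSpec",
    "IntensitySpec",
    "substream_rng",
    "simulate_pressure_trace",
    "simulate_fluorescence_experiment",
    "simulate_gravimetric",
    "simulate_intensity_stacks",
]


def substream_rng(seed: int, name: str) -> np.random.Generator:
    """Independent generator for the named substream of a global seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


@dataclass(frozen=True)
class PressureTraceSpec:
    """Stretch-run simulation: 10% peak linear strain at 0.33 Hz with the
    day-6 wet-membrane modulus of 0.78 MPa are the reference conditions."""

    duration_s: float = 60.0
    sample_rate_hz: float = 40.0
    target_linear_strain: float = 0.10
    frequency_hz: float = 0.33
    true_modulus_mpa: float = 0.78
    pressure_noise_sd_kpa: float = 0.0
    waveform: Literal["raised_cosine", "sinusoid"] = "raised_cosine"
    geometry: MembraneGeometry = field(default_factory=MembraneGeometry)
    chamber: ChamberConfig = field(default_factory=ChamberConfig)

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sample_rate_hz <= 0 or self.frequency_hz <= 0:
            raise InvalidArgumentError("duration, sample rate and frequency must be positive")
        if self.target_linear_strain < 0 or self.true_modulus_mpa <= 0:
            raise InvalidArgumentError("strain must be >= 0 and modulus > 0")
        if self.pressure_noise_sd_kpa < 0:
            raise InvalidArgumentError("pressure_noise_sd_kpa must be >= 0")


def simulate_pressure_trace(spec: PressureTraceSpec, seed: int = 0) -> PressureTrace:
    """Simulate the dual-pressure channels of one stretch run.

    Per time step the apex height follows Δh(t) = a·ε·½(1 − cos 2πft) (peak
    linear strain ε; ``"sinusoid"`` oscillates about a·ε/2 with the same peak
    instead); the cap volume gives ΔV, the linearised gas bookkeeping gives
    P2 = P0 + ΔV·P0/V0, and the bulge-test relation with the true modulus
    gives P1 = P2 + ΔP′.  Independent Gaussian sensor noise is added to both
    channels.  Deterministic under a fixed seed.
    """
    if spec.sample_rate_hz < 10.0 * spec.frequency_hz:
        raise AliasingError(
            f"sample_rate_hz={spec.sample_rate_hz} is below 10x the stretch frequency "
            f"{spec.frequency_hz} Hz; the waveform would be undersampled"
        )
    rng = substream_rng(seed, "pressure_trace")
    n = int(round(spec.duration_s * spec.sample_rate_hz)) + 1
    t = np.arange(n) / spec.sample_rate_hz
    a = spec.geometry.radius_a_cm
    phase = 2.0 * np.pi * spec.frequency_hz * t
    if spec.waveform == "raised_cosine":
        dh = a * spec.target_linear_strain * 0.5 * (1.0 - np.cos(phase))
    elif spec.waveform == "sinusoid":
        dh = a * spec.target_linear_strain * 0.5 * (1.0 + np.sin(phase))
    else:
        raise InvalidArgumentError(f"unknown waveform {spec.waveform!r}")
    dv = cap_volume(dh, a)
    p0, v0 = spec.chamber.ambient_p0_kpa, spec.chamber.headspace_v0_ml
    p2 = p0 + dv * p0 / v0
    dp_prime = pressure_modulus_coefficient(dh, spec.geometry) * spec.true_modulus_mpa
    p1 = p2 + dp_prime
    if spec.pressure_noise_sd_kpa > 0:
        p1 = p1 + rng.normal(0.0, spec.pressure_noise_sd_kpa, size=n)
        p2 = p2 + rng.normal(0.0, spec.pressure_noise_sd_kpa, size=n)
    return PressureTrace(t, p1, p2)


@dataclass(frozen=True)
class FluorescenceSpec:
    """Plate-reader translocation assay simulation.

    Defaults emulate the stretch-bioreactor configuration: 16 mL of basal
    medium (basal compartment plus reservoir), a delivered dose of 10.5 μg
    (2.1 μg cm⁻² on a 5 cm² membrane), and a true translocated fraction of
    30% — the stretched 100 nm condition.
    """

    true_fraction_percent: float = 30.0
    delivered_mass_ug: float = 10.5
    basal_volume_ml: float = 16.0
    curve_slope_au_per_ug_ml: float = 1000.0
    curve_intercept_au: float = 50.0
    curve_concentrations_ug_ml: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4, 0.8)
    relative_noise: float = 0.02
    blank_sd_au: float = 1.0
    n_blanks: int = 6
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.true_fraction_percent < 0:
            raise InvalidArgumentError("true_fraction_percent must be >= 0")
        if self.delivered_mass_ug <= 0 or self.basal_volume_ml <= 0:
            raise InvalidArgumentError("delivered mass and basal volume must be positive")
        if self.relative_noise < 0 or self.blank_sd_au < 0:
            raise InvalidArgumentError("noise levels must be >= 0")
        if self.n_blanks < 3:
            raise InvalidArgumentError("at least 3 blanks are required downstream")


def simulate_fluorescence_experiment(
    spec: FluorescenceSpec, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Simulate one translocation assay.

    Returns (standard-curve table with columns ``conc_ug_ml, fluor_au``,
    blank readings, basal readings).  The basal concentration is derived from
    the true fraction, basal volume and delivered mass; every reading gets
    multiplicative Gaussian noise of the given relative level, blanks get
    additive noise around the curve intercept.
    """
    rng = substream_rng(seed, "fluorescence")
    conc = np.asarray(spec.curve_concentrations_ug_ml, dtype=float)
    clean = spec.curve_intercept_au + spec.curve_slope_au_per_ug_ml * conc
    curve_fluo = clean * (1.0 + rng.normal(0.0, spec.relative_noise, size=conc.size))
    blanks = spec.curve_intercept_au + rng.normal(0.0, spec.blank_sd_au, size=spec.n_blanks)
    basal_conc = (
        spec.true_fraction_percent / 100.0 * spec.delivered_mass_ug / spec.basal_volume_ml
    )
    basal_clean = spec.curve_intercept_au + spec.curve_slope_au_per_ug_ml * basal_conc
    basal = basal_clean * (1.0 + rng.normal(0.0, spec.relative_noise, size=spec.n_replicates))
    return pd.DataFrame({"conc_ug_ml": conc, "fluor_au": curve_fluo}), blanks, basal


@dataclass(frozen=True)
class GravimetricSpec:
    """Liquid-displacement porosity simulation; the default true porosity is
    the reference membrane's measured 3D porosity of 15.3%."""

    true_porosity: float = 0.153
    dry_mass_mg: float = 10.0
    rho_membrane: float = 1.2
    rho_etoh: float = 0.789
    blank_apparent_porosity: float = 0.0
    weighing_noise_sd_mg: float = 0.0
    n_samples: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.true_porosity < 1:
            raise InvalidArgumentError("true_porosity must be in [0, 1)")
        if self.true_porosity + self.blank_apparent_porosity >= 1:
            raise InvalidArgumentError("true porosity plus blank must stay below 1")
        if self.dry_mass_mg <= 0 or self.rho_membrane <= 0 or self.rho_etoh <= 0:
            raise InvalidArgumentError("masses and densities must be positive")
        if self.weighing_noise_sd_mg < 0 or self.n_samples < 1:
            raise InvalidArgumentError("noise must be >= 0 and n_samples >= 1")


def simulate_gravimetric(spec: GravimetricSpec, seed: int = 0) -> list[GravimetricMeasurement]:
    """Simulate dry/soaked mass pairs whose noiseless analysis returns the
    generator porosity exactly.

    The ethanol uptake is chosen so the *raw* gravimetric porosity equals the
    true porosity plus the configured blank; the analysis stage then subtracts
    the same blank.  Weighing noise is added to the soaked mass.
    """
    rng = substream_rng(seed, "gravimetric")
    raw = spec.true_porosity + spec.blank_apparent_porosity
    v_m = spec.dry_mass_mg / spec.rho_membrane
    v_etoh = raw / (1.0 - raw) * v_m
    uptake = v_etoh * spec.rho_etoh
    out = []
    for _ in range(spec.n_samples):
        noise = rng.normal(0.0, spec.weighing_noise_sd_mg) if spec.weighing_noise_sd_mg else 0.0
        soaked = max(spec.dry_mass_mg, spec.dry_mass_mg + uptake + noise)
        out.append(
            GravimetricMeasurement(
                mass_dry_mg=spec.dry_mass_mg,
                mass_soaked_mg=soaked,
                rho_membrane=spec.rho_membrane,
                rho_etoh=spec.rho_etoh,
                blank_apparent_porosity=spec.blank_apparent_porosity,
            )
        )
    return out


@dataclass(frozen=True)
class IntensitySpec:
    """Imaging-field intensity simulation; the default condition means encode
    a 2.4-fold uptake increase over five fields per stack."""

    mean_condition_a_au: float = 240.0
    mean_condition_b_au: float = 100.0
    n_fields: int = 5
    field_noise_sd_au: float = 0.0
    n_stacks: int = 4

    def __post_init__(self) -> None:
        if self.mean_condition_a_au < 0 or self.mean_condition_b_au < 0:
            raise InvalidArgumentError("condition means must be >= 0")
        if self.n_fields < 1 or self.n_stacks < 1:
            raise InvalidArgumentError("n_fields and n_stacks must be >= 1")
        if self.field_noise_sd_au < 0:
            raise InvalidArgumentError("field_noise_sd_au must be >= 0")


def simulate_intensity_stacks(
    spec: IntensitySpec, seed: int = 0
) -> tuple[list[FieldIntensitySummary], list[FieldIntensitySummary]]:
    """Simulate per-field background-subtracted intensities for two conditions.

    Returns (condition-a stacks, condition-b stacks); field means are
    N(μ_condition, σ), floored at 0.
    """
    rng = substream_rng(seed, "intensity")

    def draw(mu: float) -> list[FieldIntensitySummary]:
        stacks = []
        for _ in range(spec.n_stacks):
            vals = mu + rng.normal(0.0, spec.field_noise_sd_au, size=spec.n_fields)
            stacks.append(FieldIntensitySummary(tuple(np.maximum(vals, 0.0))))
        return stacks

    return draw(spec.mean_condition_a_au), draw(spec.mean_condition_b_au)
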