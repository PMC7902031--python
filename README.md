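# lungstretch

Analysis toolkit for **cell-stretch lung bioreactor** experiments: cultures
of lung epithelial cells at the air–liquid interface (ALI) on a thin
circular elastic membrane that is "breathed" by cyclic positive pressure
while aerosolised particles are deposited on the cells.

It is written for the people who run and analyse such experiments and covers
the full computational chain:

- **Stretch monitoring** — infer stretch amplitude, frequency and the
  membrane's triaxial Young's modulus in real time from two pressure
  sensors. The bulging membrane is a spherical cap: the reservoir headspace
  pressure `P2` encodes the dome volume (`ΔV = (P2 − P0)·V0/P0`), the cap
  geometry `ΔV = π·Δh·(a²/2 + Δh²/6)` yields the apex height `Δh`, strain is
  `ΔL/L = Δh/a` (area strain `(1 + Δh/a)² − 1`), and the transmembrane
  pressure obeys the bulge-test relation

  `P1 − P2 = [4·E·(Δh/a)·t / (3a((Δh/a)² + 1))]·[1 − (1 + (Δh/a)²)⁻³]`,

  linear in `E`, so the modulus follows by division.
- **Membrane characterisation** — liquid-displacement porosity with blank
  correction, composition-derived theoretical porosity of PCL/gelatin
  blends, and the WST-1 / LDH / TEER / proliferation normalisations.
- **Aerosol dosimetry** — deposited mass dose (μg cm⁻²) and particle
  surface-area dose (cm² cm⁻²) from nebulization-run parameters.
- **Particokinetics** — transepithelial translocation fractions from basal
  fluorescence via a standard curve with limit-of-detection handling, and
  cellular-uptake fold changes from imaging-field intensities.
- **Breathing physiology** — map tidal volume and FRC to alveolar strain
  (spherical-alveolus model) and back, classify strain regimes, and compute
  area-to-perfusion ratios.
- **Synthetic data** — seeded generators that emulate every instrument input
  (pressure channels, plate reader, balance, imaging summaries), each the
  exact forward model of its analysis stage.

See [`docs/methods.md`](docs/methods.md) for the models, conventions and
numerical choices.

## Worked example

```python
from lungstretch import (ChamberConfig, MembraneGeometry, PressureTraceSpec,
                         analyze_trace, simulate_pressure_trace)

spec = PressureTraceSpec(pressure_noise_sd_kpa=0.01)   # 10% strain, 0.33 Hz, E=0.78 MPa
trace = simulate_pressure_trace(spec, seed=42)
report = analyze_trace(trace, MembraneGeometry(), ChamberConfig())
print(report.frequency_hz, report.strain_mean, report.modulus_mean_mpa)
```

Running `python examples/01_stretch_monitoring.py` (which is this example
with a formatted report) prints:

```
cycles detected:        20
stretch frequency:      0.331 Hz   (generator: 0.33 Hz)
peak linear strain:     0.1001 +/- 0.0002   (generator: 0.10)
Young's modulus:        0.84 +/- 2.08 MPa   (generator: 0.78)
over-stretch cycles:    0
```

The analyzer recovers the generator's frequency to the trace's resolution
and the peak linear strain to ~0.1%. The per-cycle modulus scatters widely
because the transmembrane pressure at 10% strain is only ~1.2 Pa against
10 Pa of sensor noise — the cycle-averaged value is the monitored quantity.
The other scripts in `examples/` walk through porosity, dosimetry +
translocation, and the physiology mapping the same way.

A thin CLI wraps the same functions for shell use:

```bash
lungstretch simulate --seed 1 --out run1 --fluorescence
lungstretch monitor run1/trace.csv --out run1
lungstretch translocate run1/curve.csv run1/blanks.csv run1/samples.csv
lungstretch dose            # deposited + surface-area dose for a cloud run
lungstretch physiology --pattern heavy_exercise_male
```

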