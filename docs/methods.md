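# Methods

`lungstretch` implements the computational side of a cell-stretch lung
bioreactor workflow: an air–liquid-interface (ALI) culture on a thin circular
elastic membrane is "breathed" by cyclic positive pressure, aerosolised
particles are deposited on the cells, and particle uptake and transbarrier
transport are quantified. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic generators do and do
not emulate.

## Units

Public interfaces use the bench units throughout: cm for lengths (membrane
thickness in μm), mL (= cm³) for volumes, kPa for pressures, μg for masses,
μL min⁻¹ for perfusion. These units are mutually consistent for every formula
in the package (the only conversions are μm→cm for thickness and MPa→kPa for
the modulus), so no separate internal unit system is used. All JSON/CSV
field names carry unit suffixes.

## Spherical-cap stretch model

A clamped circular membrane of radius `a` inflated from its flat state forms
a spherical cap of apex height `Δh`. The package uses:

- cap volume `ΔV = π·Δh·(a²/2 + Δh²/6)`, which equals the hemisphere volume
  `2πa³/3` at `Δh = a`;
- the inverse, found as the unique non-negative root of the monotone cubic
  `π·Δh³/6 + π·a²·Δh/2 − ΔV = 0`. The public scalar function brackets the
  root on `[0, 10a]` (Brent, `xtol = 1e−14`); trace analysis uses a
  vectorised Cardano closed form polished by one Newton step. Both agree to
  1e−10 relative tolerance and round-trip the forward formula to 1e−9.
- linear strain `ΔL/L = Δh/a`.

Two **area-strain conventions** exist for this geometry. The default,
`"text"`, is `ΔS/S = (1 + Δh/a)² − 1`, which reproduces every worked stretch
pairing in this setup (10% linear ↔ 21% area, 17% ↔ ~35–36%). The
small-deflection form `(Δh/a)²` that is sometimes printed next to the cap
formulas is available as `"eq_printed"` for fidelity but is not used by any
default path.

The monitoring electronics for this chamber were validated for apex heights
up to about `0.09·a`; the geometry module imposes no hard cap (states beyond
it are computed and the strain classifier flags them) because the worked
pressure numbers themselves imply larger deflections.

## Pressure-based monitoring

Two absolute pressure channels are recorded: `P1` (apical compartment, the
actuation side) and `P2` (sealed air headspace of the medium reservoir).
Because the culture medium is incompressible, the dome volume swept by the
membrane compresses the reservoir headspace:

- gas bookkeeping: `ΔV = (P2 − P0)·V0/P0` (linearised, default) or the exact
  isothermal form `ΔV = V0·(1 − P0/P2)`; they differ by at most `ΔP/P0`
  relatively (~1% at the reference conditions). Defaults: `P0 = 98.0 kPa`,
  `V0 = 30 mL`.
- bulge-test relation for a thin elastic membrane (thickness `t`, Young's
  modulus `E`, `x = Δh/a`):

  `ΔP′ = P1 − P2 = [4·E·x·t / (3a(x² + 1))] · [1 − (1 + x²)⁻³]`

  `ΔP′` is linear in `E`, so the modulus inversion divides the measured
  transmembrane pressure by a purely geometric coefficient `k(Δh)`; the
  inversion is singular at `Δh = 0` and raises accordingly.

**A magnitude caveat, implemented verbatim.** With the reference values
(`E = 0.78 MPa`, `t = 5 μm`, `a = 1.26 cm`) the relation predicts
`ΔP′ ≈ 1.2 Pa` at 10% linear strain, three orders of magnitude below the
~1 kPa apical overpressures the hardware applies. The package implements the
printed relation as-is and documents the tension rather than rescaling
anything; all modulus tests are therefore internal forward/inverse round
trips and generator closed loops, not the worked pressure pairing.
Similarly, the gas bookkeeping at `P2 = 99.5 kPa` implies ~14.5% linear
strain rather than the nominal 10%, so trace-level validation uses
self-consistent synthetic traces.

### Trace analysis (`analyze_trace`)

Per sample: `ΔV` from `P2` (clamped to zero below ambient and flagged, never
dropped), `Δh` by cap inversion, strains, `ΔP′ = P1 − P2`. Cycle detection
runs on mean-subtracted `P2`: the dominant period comes from the
autocorrelation maximum beyond its first zero crossing, then local maxima
with prominence ≥ 25% of the peak-to-trough range and minimum separation
0.4× that period. Frequency is `1/median(peak spacing)`; fewer than two
detected cycles raises an error that still carries the per-sample table.

Per-cycle estimation is built so that sensor noise does not bias it, which
matters because the modulus signal (`ΔP′` ~ Pa) can sit well below the noise
(σ ~ 0.01 kPa):

- **cycle anchors** come from a regular grid `t0 + k·T` least-squares fitted
  to the detected peak times. A raw `argmax` anchor is the sample with the
  most favourable noise draw, and conditioning on it biases `ΔP′` at and
  around that sample; each peak contributes only `1/n` to the grid, which
  removes the coupling.
- **peak strain** per cycle is `b0 + √(b1² + b2²)` from a least-squares fit
  of `b0 + b1·cos ωt + b2·sin ωt` over the cycle window (ω from the
  frequency estimate), computed on the signed (unclamped) deflection so the
  noise stays zero-mean through the nonlinearity. The estimator is exact for
  any sinusoidal actuation regardless of how the sampling grid falls, and
  linear in the data, hence unbiased; its only bias term, the norm's Jensen
  correction, is ~1e−7 at the reference noise.
- **modulus** per cycle (default `"peak"`) is the ratio of window sums
  `ΣΔP′ / Σk(Δh)` over ±⅛ period around the grid anchor — exactly `E` for
  noiseless data because `ΔP′ = k·E` pointwise, and the zero-mean noise in
  the numerator averages out. A `"plateau"` option instead averages
  `ΔP′/k` over all samples above 50% of the cycle's peak deflection.
- strain classification: > 17% linear flags over-stretch, > 25% flags
  exceeding the membrane's reversible-strain tolerance (both configurable).

Measured on the synthetic closed loop (60 s, 0.33 Hz, 10% strain,
E = 0.78 MPa): noiseless recovery is exact to ≪1% for all three parameters;
at σ = 0.01 kPa the mean recovered modulus carries a residual bias of
~+0.03 MPa (second-order noise terms in `k`), well inside the Monte-Carlo
3-SE band at 50 seeds.

## Porosity models

- **Empirical (liquid displacement):** soak in ethanol, then
  `V_EtOH = (m_soaked − m_dry)/ρ_EtOH` (ρ = 0.789 g cm⁻³),
  `V_m = m_dry/ρ_membrane`, porosity `= V_EtOH/(V_EtOH + V_m)`. The apparent
  porosity of a pure-PCL membrane measured the same way (default 9.3%,
  ethanol adsorption plus intrinsic microporosity) is subtracted; negative
  corrected values clamp to zero with a warning.
- **Theoretical (composition):** the gelatin volume fraction
  `(c_gel/ρ_gel) / (c_gel/ρ_gel + c_PCL/ρ_PCL)` with `c` the mass amounts
  per unit solvent volume. Written with "volume fractions" in place of the
  `c` values this expression is dimensionally inconsistent; the mass-based
  reading is the one that reproduces the reference blend's quoted value and
  is what the package implements. Two PCL densities circulate in the
  literature for this material (1.145 and 1.45 g cm⁻³); 1.145 is the
  default because it is the value used by the gravimetric analysis and the
  only one consistent with the reference blend's quoted 37.6% (the package
  computes 37.4%; the final-digit gap is attributable to unprinted density
  precision). Both densities are plain parameters.

Assay normalisations (WST-1 viability, LDH release as percent of the
full-lysis dose, TEER with blank-membrane subtraction, proliferation fold)
are the standard linear forms; TEER deliberately does not clamp at zero
since non-positive values are the "no barrier" signal.

## Dosimetry

Deposited mass dose = nebulized volume × suspension concentration ×
deposition factor / exposure area. Surface-area dose for monodisperse
spheres multiplies by the specific surface area `6/(ρ·d)`; polystyrene
density defaults to 1.05 g cm⁻³ (standard material constant, overridable).
The stretch bioreactor's integrated nebulizer deposits a fixed 52% of the
nebulized mass onto its 5 cm² membrane; the suspension concentration for
those runs is not independently recorded, so the matched 2.1 μg cm⁻² dose is
taken as the delivered dose and the nebulized mass back-calculated when
needed. Doses are reported unrounded plus rounded to conventional precision
(one decimal for mass dose, two significant figures for surface-area dose).

## Translocation and uptake

The standard curve is ordinary least squares with a free intercept (culture
medium autofluoresces; a through-origin option exists). The limit of
detection uses the conventional spectroscopy rule
`LOD = (mean(blanks) + 3·SD(blanks) − intercept)/slope`, floored at zero.
The translocated fraction is `100·c·V_basal/m_delivered` with
`c = (F − intercept)/slope`, normalised to the **cell-delivered** dose.
Readings at or below blank level, or below the LOD, are flagged and carry
the LOD-equivalent fraction as an upper bound — below-LOD results are never
reported as zero. Uptake is the mean (±SD) over imaging fields of
background-subtracted mean intensities; condition comparisons are reported
as fold changes to one decimal.

## Synthetic generators

Each generator is the exact forward model of its analysis stage:

- **pressure traces:** `Δh(t) = a·ε·½(1 − cos 2πft)` (raised cosine: the
  membrane returns to flat each cycle, matching positive-pressure actuation
  from a relaxed state; an offset sinusoid with the same peak is the
  alternative), pushed through cap volume → linearised gas law → bulge-test
  relation, plus independent Gaussian noise on both channels. Requesting a
  sample rate below 10× the stretch frequency raises an aliasing error.
  Defaults are the reference bench conditions: 60 s, 40 Hz sampling, 10%
  strain, 0.33 Hz, E = 0.78 MPa, noiseless unless asked.
- **fluorescence assays:** readings linear in concentration with
  multiplicative 2% noise (plate-reader-like), a six-blank population with
  1 AU additive scatter, curve levels 0.05–0.8 μg mL⁻¹ spanning the basal
  concentrations the defaults produce; delivered mass 10.5 μg (2.1 μg cm⁻²
  on 5 cm²) into 16 mL of basal medium (basal compartment plus reservoir),
  true fraction 30% — the stretched 100 nm condition.
- **gravimetric series:** ethanol uptake chosen so the raw porosity equals
  the true value plus the configured blank, plus weighing noise on the
  soaked mass.
- **intensity stacks:** per-field means `N(μ_condition, σ)` floored at 0;
  default means encode a 2.4-fold stretched/static uptake ratio over five
  fields per stack, four stacks per condition.

One global seed fans out to named substreams (`SeedSequence([seed,
crc32(name)])`), so adding a generator call never perturbs another stream.

**What the generators do not emulate:** sensor drift and hysteresis,
valve/controller dynamics, non-sinusoidal actuation, membrane viscoelasticity
or creep, evaporation and volume loss in the basal medium, photobleaching,
spatially heterogeneous deposition, or biological variability between
membranes and cultures. Passing closed-loop tests therefore demonstrates
that the analysis inverts its own measurement model correctly and without
bias at realistic noise levels — not that real instruments satisfy that
model.

## Problem sizes in tests

The recovery suites use 60 s traces at 40 Hz (≈20 cycles) over 50 noise
seeds for the stretch loop and 200 simulated assays (3 replicates each) for
the translocation loop — enough cycles/replicates for the 3-SE Monte-Carlo
bands to be meaningful while the whole suite stays fast.

## Known limitations

- The bulge-test magnitude inconsistency above means absolute moduli from
  real traces of this hardware should be interpreted against the printed
  relation's scale, not against uniaxial tensile values.
- Frequency estimation assumes a single dominant stretch frequency; mixed
  or swept-frequency protocols are out of scope.
- The harmonic peak-strain estimator assumes sinusoidal actuation; for
  strongly non-sinusoidal waveforms the per-cycle maxima in the sample table
  are the more faithful (if noisier) quantity.
- Translocation is a single-endpoint measurement; no kinetic transport
  modelling is attempted.
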