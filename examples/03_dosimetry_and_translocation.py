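"""Aerosol dose bookkeeping and the translocation assay.

Computes the deposited dose of a cloud-settling nebulization run, then runs
the fluorescence-based translocation pipeline on a synthetic assay generated
at a 30% true translocated fraction (the stretched 100 nm condition).
"""

from lungstretch import (
    FluorescenceSpec,
    NebulizationRun,
    ParticleSpec,
    civic_delivered_mass,
    deposited_mass_dose,
    fit_standard_curve,
    simulate_fluorescence_experiment,
    surface_area_dose,
    translocated_fraction,
)

run = NebulizationRun(
    nebulized_volume_ul=250.0,
    suspension_concentration_mg_ml=1.25,
    deposition_factor=0.97,
    exposure_area_cm2=146.0,
)
mass = deposited_mass_dose(run)
print(f"deposited mass dose:      {mass:.2f} ug/cm2  (rounds to 2.1)")
print(f"surface-area dose 100 nm: {surface_area_dose(mass, ParticleSpec(100)):.2f} cm2/cm2")
print(f"surface-area dose 1 um:   {surface_area_dose(mass, ParticleSpec(1000)):.3f} cm2/cm2")

total, dose = civic_delivered_mass(20.2, efficiency=0.52, membrane_area_cm2=5.0)
print(f"bioreactor delivery:      {total:.1f} ug total -> {dose:.1f} ug/cm2 on the membrane")
print()

spec = FluorescenceSpec(true_fraction_percent=30.0)
curve_df, blanks, basal = simulate_fluorescence_experiment(spec, seed=11)
curve = fit_standard_curve(curve_df["conc_ug_ml"], curve_df["fluor_au"], blanks)
print(f"standard curve: slope {curve.slope_au_per_ug_ml:.0f} AU/(ug/mL), "
      f"LOD {curve.lod_concentration_ug_ml:.4f} ug/mL")
for reading in basal:
    r = translocated_fraction(reading, curve, spec.basal_volume_ml, spec.delivered_mass_ug)
    print(f"  basal reading {reading:7.1f} AU -> {r}")
print()
print("Fractions are percentages of the cell-delivered dose recovered in the")
print("basal medium after 2 h; readings indistinguishable from blank would be")
print("reported as '<LOD (x%)' with the detection limit as an upper bound.")
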