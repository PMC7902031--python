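"""Porosity of a PCL/gelatin membrane, empirically and from composition.

The gravimetric route soaks the membrane in ethanol and converts the mass
uptake into pore volume; the composition route gives the theoretical upper
limit — the gelatin volume fraction that would become pore space if every
gelatin island dissolved.
"""

from lungstretch import (
    GravimetricSpec,
    MembraneComposition,
    empirical_porosity,
    simulate_gravimetric,
    theoretical_porosity,
)

# reference blend: 9.35% PCL, 6.34% gelatin (w/v of solvent)
comp = MembraneComposition(9.35, 6.34)
print(f"theoretical (max) porosity: {100 * theoretical_porosity(comp):.1f} %")
print(f"blend mixture density:      {comp.mixture_density():.3f} g/cm3")

# synthetic gravimetric series at the membrane's measured 3D porosity (15.3%)
spec = GravimetricSpec(true_porosity=0.153, weighing_noise_sd_mg=0.05, n_samples=5)
values = [empirical_porosity(g) for g in simulate_gravimetric(spec, seed=0)]
mean = sum(values) / len(values)
print(f"empirical porosity (n=5):   {100 * mean:.1f} %   (generator: 15.3 %)")
print()
print("The gap between ~15% measured and ~37% theoretical porosity means")
print("most gelatin islands are fully engulfed by PCL and never reached by")
print("the medium — only the connected fraction becomes through-pores.")
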