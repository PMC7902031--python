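"""Relate bench stretch settings to breathing physiology.

Maps ICRP population-average breathing patterns to the alveolar strain they
imply (spherical-alveolus model), and a bench strain setting back to the
tidal volume it emulates.
"""

from lungstretch import (
    ICRP_PATTERNS,
    area_perfusion_ratio,
    classify_strain,
    strain_from_volume_expansion,
    tidal_volume_from_linear_strain,
    volume_expansion,
)

for name, pattern in ICRP_PATTERNS.items():
    f = volume_expansion(pattern)
    linear, area = strain_from_volume_expansion(f)
    regime = classify_strain(linear).value
    print(
        f"{name:24s} VT={pattern.tidal_volume_l:.2f} L  "
        f"expansion {100 * f:4.0f} %  linear {100 * linear:4.1f} %  "
        f"area {100 * area:4.1f} %  [{regime}]"
    )

print()
tv_m = tidal_volume_from_linear_strain(0.10, 3.3)
tv_f = tidal_volume_from_linear_strain(0.10, 2.7)
print(f"bench 10% linear strain ~ tidal volume {tv_m:.2f} L (male) / {tv_f:.2f} L (female)")
print(f"bioreactor area/perfusion ratio: {area_perfusion_ratio(5.0, 400.0):.2f} m2 per L/min")
print("(the lung's ratio is ~20 m2 per L/min: 100 m2 over ~5 L/min at rest)")
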