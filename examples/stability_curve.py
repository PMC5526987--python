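"""Quantify halo decay over timed series and plot survival as text.

Simulates 16 cells imaged at 0-60 s in 10 s steps whose peak intensity
decays exponentially at per-cell random rates, measures each with the
x75/x180 thresholds (failure = outer threshold unreachable), and prints
the surviving-halo curve and mean time to decay (censored cells count 70 s).
"""

import numpy as np

from halokit import ThresholdConfig, decay_record, mean_time_to_decay, surviving_fraction
from halokit import synthgen as sg

rng = np.random.default_rng(5)
config = ThresholdConfig.from_shorthand("x75/x180", min_object_area_px=200)

records = []
for i in range(16):
    spec = sg.sample_decay_spec(rng, outer_value=180)
    series, analytic = sg.render_timeseries(spec, cell_id=f"cell{i}", outer_value=180)
    rec = decay_record(series, config)
    records.append(rec)
    mark = "censored" if rec.censored else f"fails at {rec.fail_time_s:g} s"
    agree = "ok" if rec.fail_time_s == (70.0 if analytic is None else analytic) else "MISMATCH"
    print(f"{rec.cell_id:>7}: rate {spec.decay_rate_per_s:.4f}/s  {mark:<14} [{agree}]")

times = [0, 10, 20, 30, 40, 50, 60]
print("\nsurviving halos (% of population):")
for t, pct in surviving_fraction(records, times):
    print(f"  t = {t:>4.0f} s  {pct:5.1f}%  {'#' * int(pct // 4)}")

mean, sem = mean_time_to_decay(records)
print(f"\nmean time to decay: {mean:.1f} s (SEM {sem:.1f} s, n = {len(records)})")
print("Stable populations sit near 70 s (the censor sentinel); rapidly decaying")
print("ones fail early, pulling the mean down and the survival curve steeper.")
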