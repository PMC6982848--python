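"""Simulate a full plot survey and score how well the method recovers truth.

Generates a 10 x 10 m plot on a 20-degree slope with a realistic mix of
stem cross-sections, simulates the field protocol (two caliper directions
and two UWB observations per tree) under the default sensor-noise model,
runs the estimators, and prints the accuracy tables that a real campaign
would report: DBH bias/RMSE and per-axis position errors plus the
point-distance error Ed.
"""

import numpy as np

from stemsurvey import NoiseModel, generate_plot, run_recovery_experiment
from stemsurvey.simulator import ZERO_NOISE

plot = generate_plot(n_trees=25, slope_deg=20.0, seed=7)
s = plot.summary()
print(f"plot: {s['n_trees']} trees, slope {s['slope_deg']:.0f} deg, "
      f"DBH {s['dbh_min_mm']:.0f}-{s['dbh_max_mm']:.0f} mm "
      f"(mean {s['dbh_mean_mm']:.0f})\n")

print("--- noise-free run (structural check) ---")
res0 = run_recovery_experiment(plot, ZERO_NOISE, seed=1)
r = res0.records
print(f"max |DBH error|      : {(r.dbh_mm - r.dbh_ref_mm).abs().max():.2e} mm "
      "(only elliptical stems deviate: they lie outside the two-arc model)")
print(f"max position error   : "
      f"{np.hypot(r.x_cm - r.x_ref_cm, r.y_cm - r.y_ref_cm).max():.2e} cm\n")

print("--- default sensor noise (10 cm range sd + 10 cm NLOS, 2 cm alt, 0.1 deg) ---")
res = run_recovery_experiment(plot, NoiseModel(), seed=1)
print(res.dbh_summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print(res.position_summary.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print("\nBIAS near zero and RMSE a fraction of a millimetre show the caliper "
      "geometry adds no systematic error; position errors of ~10 cm reflect "
      "the UWB noise model after trilateration, fusion and averaging.")
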