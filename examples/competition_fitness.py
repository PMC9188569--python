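"""Competition-assay fitness inference on the virtual turbidostat.

Runs a his3-mutant vs WT competition at a high OD setpoint with 20 uM
histidine feed (nutrient-scarce once the culture is dense), samples
cytometry-sized counts every 2 h, detects the steady-state window where
the log-odds is linear, and reads off the growth-rate difference.
"""

import numpy as np

from reacloop.fitness import RatioSeries, detect_steady_window, estimate_fitness_difference
from reacloop.virtual_lab import GrowthModel, Strain, delta_mu_curve, run_competition

model = GrowthModel(
    strains=(
        Strain("mutant", mu_max=0.4, his_dependent=True),
        Strain("wt", mu_max=0.4),
    ),
    h_in=20.0,  # uM histidine in the feed
)

ods = [0.1, 0.3, 0.5, 0.6, 0.7, 0.8]
curve = delta_mu_curve(model, ods)
print("steady-state WT advantage vs OD setpoint (20 uM feed):")
for od, dmu in zip(ods, curve):
    print(f"  OD {od:.1f}: delta_mu = {dmu:+.3f} /h")

times, fractions, _ = run_competition(model, od_setpoint=0.8, duration_h=24.0)
counts = np.column_stack([fractions, 1 - fractions]) * 10000  # mutant:wt counts
series = RatioSeries(times, counts)
window = detect_steady_window(series, tolerance=0.05)
est = estimate_fitness_difference(series, window)
print(f"\ncompetition at OD 0.8: steady window = samples {window.start}..{window.stop - 1}")
print(f"log-odds slope (mutant vs wt): {est.delta_mu:+.3f} +/- {est.stderr:.3f} /h")
print("Near OD 0.8 the residual histidine collapses, the mutant arrests, and")
print("the slope approaches -mu_wt = -0.4 /h; below OD ~0.6 the advantage is ~0.")
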