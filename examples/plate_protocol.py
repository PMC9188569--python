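"""Plate-reader bookkeeping: evaporation-compensated dilutions.

Demonstrates the robot protocol arithmetic: wells evaporate at 10 uL/h;
when the median blank-subtracted OD crosses the threshold, 100 uL of
media is added and 100 uL minus the estimated evaporation removed, so
the volume returns exactly to nominal. Also shows antibiotic treatment
by conservation and the early-OD artifact filter.
"""

from dataclasses import replace

import numpy as np

from reacloop.virtual_lab import (
    PlateState,
    Well,
    clean_od,
    evaporate,
    plate_dilution_protocol,
    treat_well,
)

plate = PlateState(wells=(Well(od=0.12),), blank_od=0.0)
print("cycle  volume(uL)  OD(before)  action   OD(after)")
for cycle in range(1, 5):
    plate = evaporate(plate, 1.0)
    plate = replace(plate, wells=(replace(plate.wells[0], od=0.12),))  # growth
    od_before = plate.wells[0].od
    action, plate = plate_dilution_protocol(plate, threshold=0.1)
    print(f"{cycle:5d}  {plate.wells[0].volume:9.1f}  {od_before:10.4f}  "
          f"{action.kind:7s}  {plate.wells[0].od:.4f}")

plate = treat_well(plate, 0, dose=80.0)  # 50 uL at 80 mg/L into 200 uL
print(f"after treatment: antibiotic = {plate.wells[0].antibiotic:.1f} mg/L "
      "(16 mg/L final, by conservation)")

t = np.arange(0.0, 5.0, 0.5)
od = np.full(t.size, 1.2e-3)
od[[1, 3]] = 5e-3  # aberrant early readings
cleaned = clean_od(t, od, blank=1e-3)
print(f"OD series: {t.size} points, removed {cleaned.n_removed} early artifacts "
      "(raw OD600 > 3e-3 within the first 2 h)")
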