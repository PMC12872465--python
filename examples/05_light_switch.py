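"""Light-pulse periodicity switching through photoacid pH forcing.

A merocyanine photoacid couples blue-light pulses to transient pH drops
(up to 3.5 units), which modulate enzyme activities.  The reservoir is
driven with pulse trains of different periodicity (equal duty) at
800 ul/h and 30 C; a classifier on the cumulative fragment response
decides whether the period exceeds a boundary P0.
"""

import numpy as np

from enzyres import LightSchedule, Protocol, build_reservoir, evaluate_task, light_scenario
from enzyres.kinetics import LightPHTrace, PhotoacidParams
from enzyres.scenarios import light_period_grid
from enzyres.tasks import make_task

# what one pulse train does to the pH
sched = LightSchedule(period_s=120.0, duty=0.5, duration_min=4.0)
trace = LightPHTrace(sched, PhotoacidParams(), baseline_ph=7.4)
t = np.array([0.0, 30.0, 60.0, 90.0, 120.0])
print("pH under a 120-s pulse train:",
      ", ".join(f"t={ti:.0f}s pH={trace(ti):.2f}" for ti in t))

reservoir = build_reservoir(seed=0)
print("\nsimulating 17 periodicities (30-600 s) x 2 repeats "
      "(15-min pulse trains)...")
table = light_scenario(reservoir, seed=1)

periods = light_period_grid()
protocol = Protocol(repeats=20, stratified=True, seed=0)
for p0 in (periods[5], periods[8], periods[11]):
    rep = evaluate_task(table, make_task("light_switch", p0_s=float(p0)),
                        protocol=protocol)
    print(f"switch at P0 = {p0:5.0f} s: mean transformed Phi = {rep.mean:.3f}")

print("\nAlthough every pulse train delivers the same cumulative light dose,"
      "\nthe nonlinear kinetics rectify fast vs slow pH oscillations into"
      "\ndistinct fragment profiles, so the readout can tell periods apart.")
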