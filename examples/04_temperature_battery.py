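"""Temperature information processing: sensing, activation, tuning, decision.

The reservoir runs over 21 temperatures (25.5-55 C) in quadruplicate.
A ridge readout then performs linear sensing (report T), the logistic
activation task, the bell-shaped tuning task, and — with a classifier —
the threshold decision task, all from the same dataset.
"""

import numpy as np

from enzyres import Protocol, build_reservoir, evaluate_task, temperature_scenario
from enzyres.tasks import make_task, t0_grid

reservoir = build_reservoir(seed=0)
print("simulating the 21-level temperature grid x 4 replicates...")
table = temperature_scenario(reservoir, seed=1)

regress = Protocol(repeats=20, stratified=False, seed=0)
classify = Protocol(repeats=20, stratified=True, seed=0)

sensing = evaluate_task(table, make_task("sensing"), protocol=regress,
                        snr_group_key="T_C")
print(f"\nsensing: pooled R^2 = {sensing.pooled_r2:.3f}, "
      f"sensor error = {sensing.sensor_sd:.2f} C "
      f"(RMSE variant {sensing.sensor_rmse:.2f} C)")

t0 = 41.25  # one boundary from the T0 grid (30.75 ... 50.25 C)
assert np.isclose(t0_grid(), t0).any()
for name in ("activation", "tuning"):
    rep = evaluate_task(table, make_task(name, t0=t0, k=1.0), protocol=regress,
                        snr_group_key="T_C")
    print(f"{name} (T0={t0} C): pooled R^2 = {rep.pooled_r2:.3f}")
decision = evaluate_task(table, make_task("threshold", t0=t0), protocol=classify,
                         snr_group_key="T_C")
print(f"decision (T0={t0} C): mean transformed Phi = {decision.mean:.3f}")

print("\nTuning trails activation: the bell target doubles the nonlinearity"
      "\nthe linear readout must extract from the reservoir response.")
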