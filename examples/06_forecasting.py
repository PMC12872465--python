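"""Short-term forecasting of a sine-modulated substrate input.

The S1 inflow follows a sine wave; the reservoir state is sampled every
4.5 min over 7 h.  A ridge readout trained to map the current fragment
vector to the input value 9 or 13.5 min in the future exploits the
reactor's intrinsic memory (residence time V/phi = 15 min).
"""

import pandas as pd

from enzyres import FeatureTable, Protocol, build_reservoir, evaluate_task, sine_forecast_scenario
from enzyres.tasks import TaskSpec, forecast_target, lead_steps

reservoir = build_reservoir(seed=0)
print("simulating a 7-h run with sine-modulated S1 inflow (period 60 min)...")
table = sine_forecast_scenario(reservoir, seed=1)
signal = table.data["meta_input_uM"].to_numpy()

for lead_min in (9.0, 13.5):
    steps = lead_steps(lead_min)  # 4.5-min sampling grid
    idx, target = forecast_target(signal, steps)
    paired = FeatureTable(pd.concat(
        [pd.DataFrame({"meta_target": target}),
         table.features.iloc[idx].reset_index(drop=True)], axis=1))
    task = TaskSpec("forecast", "continuous", (("target", None),), lambda v: v)
    rep = evaluate_task(paired, task,
                        protocol=Protocol(repeats=10, stratified=False, seed=0))
    print(f"forecast {lead_min:5.1f} min ahead ({steps} samples): "
          f"pooled R^2 = {rep.pooled_r2:.3f} over {len(target)} pairs")

print("\nR^2 near 1 means the readout reconstructs the future inflow from"
      "\nthe current chemical state — short-term temporal processing.")
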