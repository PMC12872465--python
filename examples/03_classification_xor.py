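"""Nonlinear classification of substrate inputs (XOR / circle / hourglass).

Sixty random (S1, S2) input mixtures are fed to the simulated reservoir;
a linear classifier trained on the measured fragment features solves
classification geometries that are linearly inseparable in the raw 2-D
input space.  Scores are mean transformed Phi ((MCC+1)/2) over repeated
stratified leave-5-out cross-validation; 0.5 is chance, 1.0 is perfect.
"""

from enzyres import Protocol, build_reservoir, classification_scenario, evaluate_task
from enzyres.tasks import make_task

reservoir = build_reservoir(seed=0)
print("simulating 60 steady-state samples (S1 40-100 uM x S2 15-75 uM)...")
table = classification_scenario(reservoir, n_samples=60, seed=1)

protocol = Protocol(repeats=10, batch_size=5, stratified=True, seed=0)
print(f"{'task':10s} {'reservoir':>10s} {'raw-input':>10s}")
for name in ("xor", "circle", "hourglass"):
    report = evaluate_task(table, make_task(name), protocol=protocol, baseline=True)
    print(f"{name:10s} {report.mean:10.3f} {report.baseline.mean:10.3f}")

print("\nThe raw-input column trains the same classifier on the normalized"
      "\n(S1, S2) coordinates alone: XOR and hourglass stay at chance (~0.5)"
      "\nwithout the reservoir's nonlinear feature expansion.")
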