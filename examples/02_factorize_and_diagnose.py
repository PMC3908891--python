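"""Factorize a planted temporal network and diagnose the model order.

Generates a clean 3-group benchmark with alternating activity schedules,
runs the multi-restart non-negative factorization at several component
counts, and prints the core-consistency table used to locate the crossover
between well-specified and redundant models.
"""

import numpy as np

import tenec

# three groups of five nodes, each active every third interval
groups = {f"G{g}": tuple(f"g{g}n{i}" for i in range(5)) for g in range(3)}
schedule = {}
for g in range(3):
    probs = np.zeros(12)
    probs[g::3] = 1.0
    schedule[f"G{g}"] = probs
spec = tenec.PlantedSpec(groups=groups, schedule=schedule, n_intervals=12,
                         p_in=1.0, p_noise=0.0, seed=1)
data = tenec.generate(spec)
values = data.tensor.values
print(f"planted tensor: {values.shape}, {int(values.sum() / 2)} link-slots")

config = tenec.SolverConfig(rank=2, n_runs=4, seed=0, max_iter=200)
report = tenec.consistency_sweep(values, range(2, 7), config, keep_cc=4, keep_score=1)
print("\n R  best core consistency (selected run)")
selected = report.table[report.table["stage"] == "selected"]
for rank, sub in selected.groupby("rank"):
    print(f"{rank:>2}  {sub['core_consistency'].max():7.2f}")
print("\nCore consistency stays ~100 while R does not exceed the 3 planted")
print("groups and drops sharply once extra components become redundant —")
print("the crossover marks the largest well-supported model order.")
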