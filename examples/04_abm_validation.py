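"""Validate the deterministic recursions with an agent-based simulation.

A finite population of explicit spiders plays the converged equilibrium
strategy; its class trajectories and realized mean male fitness (from the
fair-raffle paternity at oviposition) must match the mean-field forward
pass and the dynamic-programming value within Monte-Carlo error.
"""

import numpy as np

import monogyny as mg
from monogyny import ABMConfig, simulate_abm

params = mg.default_parameters()
eq = mg.solve(params)
abm = simulate_abm(params, eq.resident, ABMConfig(n_initial_females=50_000, seed=11, replicates=2))

v = eq.values.value(mg.VIRGIN, 1)
print(f"dynamic-programming value V[virgin, 1]      : {v:.4f}")
print(f"agent-based mean male fitness (n = 50k x 2) : "
      f"{abm.male_mean_fitness:.4f} +- {abm.male_fitness_se:.4f}")

worst = 0.0
for _, row in abm.class_frequencies.iterrows():
    rec = eq.env.record(int(row.t))
    i = 0 if row.female_size == mg.SMALL else 1
    mf = rec.D[i, 0].sum() if row.female_status == mg.VIRGIN else rec.D[i, 1:].sum()
    worst = max(worst, abs(row.frequency - mf) / max(row.se, 1e-9))
print(f"worst class-frequency deviation from the mean field: {worst:.2f} standard errors")
print("\nAgreement within a few standard errors confirms that the infinite-"
      "\npopulation recursions and the stochastic individual-level model"
      "\ndescribe the same season.")
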