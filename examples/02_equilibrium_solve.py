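"""Solve for the evolutionarily stable mating strategy at the defaults.

Alternates the mean-field forward season and backward dynamic programming
until the error-smoothed best response reproduces the resident strategy,
then summarizes who males accept and how matings end (killed during the
first copulation = monogyny 1; double mating with the same female =
monogyny 2; leaving after one copulation = bigyny).
"""

import monogyny as mg

params = mg.default_parameters()
eq = mg.solve(params)
print(f"converged: {eq.converged} after {eq.iterations} iterations "
      f"(residual {eq.residual:.2e})")
print(f"reproductive value of a virgin male at season start: "
      f"{eq.values.value(mg.VIRGIN, 1):.4f} offspring")

print("\nSeason-aggregated acceptance (probability a male mates on meeting her):")
print(mg.season_aggregated_acceptance(eq).to_string(index=False, float_format="%.3f"))

print("\nSeason-aggregated outcomes of virgin-male matings:")
print(mg.season_aggregated_outcomes(eq).to_string(index=False, float_format="%.3f"))

print(
    "\nReading: virgin females are almost never rejected while mated females\n"
    "often are, and mated males reject mated females far more than virgin\n"
    "males do; terminal investment (monogyny) concentrates on large virgin\n"
    "females, while matings with small or already-mated females mostly end\n"
    "in bigyny."
)
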