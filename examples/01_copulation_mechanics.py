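"""Single-copulation mechanics: cannibalism risk and sperm economics.

A male attempting to copulate for c seconds survives with probability
1 - c/10 (the female attacks at a uniformly random tick of the first ten
seconds).  If killed, he keeps transferring sperm for delta_extension
seconds beyond the attack; a previously used genital opening voids the
whole transfer with probability `plug`.
"""

import monogyny as mg

params = mg.default_parameters()

print("c  P(survive)  E[sperm | unused]  E[sperm | used]")
for c in range(11):
    print(
        f"{c:>2}  {mg.survival_probability(c):>10.2f}"
        f"  {mg.expected_sperm(c, False, params):>17.2f}"
        f"  {mg.expected_sperm(c, True, params):>15.2f}"
    )

print()
print("Full outcome distribution for a 3-second attempt, unused opening:")
print(mg.outcome_distribution(3, False, params).to_frame().to_string(index=False))
print()
print(
    "Escaping costs sperm but preserves the second pedipalp: committing to\n"
    "the full 10 seconds is certain death yet transfers 15.5 units on\n"
    "average, versus 5.7 for a 3-second attempt that is survived 70% of\n"
    "the time.  Into a used (plugged) opening the 10-second expectation\n"
    "collapses to 3.1 units."
)
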