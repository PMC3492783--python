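# monogyny

A state-dependent dynamic game model of **conditional monogyny in
sexually cannibalistic spiders**, for behavioral ecologists and
evolutionary game theorists.

Males of the wasp spider *Argiope bruennichi* can copulate at most twice in
their life — once with each pedipalp — and every copulation risks death by
sexual cannibalism. A male meeting a female must decide whether to mate at
all, how long to keep copulating (longer transfers more sperm but raises
the chance the female kills him), and, if he survives, whether to spend his
second and final copulation on the same female or leave to search for
another (*bigyny*). This package computes the evolutionarily stable
resolution of those decisions as a function of male and female state and
the progression of the mating season, and reproduces the qualitative
predictions: terminal investment on large virgin females, rejection of
mated females (especially by mated males), and less bigyny late in the
season and under male-biased sex ratios.

## The model

A season of `t_max` discrete steps over an infinite population, with `R`
males per female and `S` web sites per female (one adult female per site).
Searching males visit sites in proportion to pheromone attractiveness
(`a_virgin : a_mated : 1` for virgin-occupied, mated-occupied and empty
sites). A male attempting to copulate for `c ∈ {0,…,10}` seconds:

* survives with probability `1 − c/10` (the female attacks at a uniform
  tick of the first 10 s); if attacked he cannot disengage and transfers
  for `Δ` further seconds,
* transfers one unit of sperm per second; a copulation into a previously
  used genital opening transfers nothing with probability `plug`
  (mating-plug failure is all-or-nothing),
* is constrained by ipsilateral insemination: left pedipalp to left
  opening, so a second copulation with the same female is forced onto her
  other side.

Paternity follows a **fair raffle** — a male's share of a female's clutch
is his fraction of the sperm she stores at oviposition — weighted by
size-dependent fecundity (small females lay `fecundity_small` of a large
female's eggs). Male reproductive values `V(state, t)` are computed by
backward dynamic programming against the season environment generated by
the resident strategy (class frequencies, stored-sperm distributions, and
a forward-looking sperm-competition kernel), including the rivals that may
reach the same female within the same time step. Decisions are
error-smoothed with exponential weights `exp(−(V* − Q(c)) / (δ·V*))`
(δ = 0.1), and alternating forward/backward passes with damping converge
to a strategy that is a smoothed best response to itself — an
error-tolerant ESS.

## Worked example

```python
import monogyny as mg

eq = mg.solve(mg.default_parameters())
print(eq.iterations, eq.residual)          # 25  5.12e-07
print(eq.values.value(mg.VIRGIN, 1))       # 0.5956
print(mg.season_aggregated_outcomes(eq))
```

which prints (columns: conditional outcome probabilities of a virgin male's
matings, aggregated over the season):

```
female_status female_size  weight  monogyny1  monogyny2  bigyny
        mated       large   0.015      0.307      0.041   0.652
        mated       small   0.011      0.256      0.015   0.729
       virgin       large   0.522      0.364      0.190   0.447
       virgin       small   0.441      0.252      0.040   0.708
          any         any   0.990      0.312      0.119   0.569
```

A virgin male at season start expects 0.5956 offspring. Once he decides to
mate, `monogyny1` is the probability he is cannibalized during that first
copulation, `monogyny2` that he survives and immediately mates the same
female again, and `bigyny` that he leaves her to search — the three always
sum to one. Terminal investment (both monogyny types) concentrates on
large virgin females (bigyny 0.447), while matings with small or mated
females mostly end in bigyny (0.65–0.73). The same equilibrium yields
acceptance probabilities per situation (`mg.acceptance_table`), the full
smoothed strategy (`eq.resident.to_frame()`), and values by state and time
(`mg.backward_induction`).

The `examples/` scripts walk one capability each: copulation mechanics,
the default equilibrium, a sex-ratio sweep, and the agent-based validation
(`python examples/02_equilibrium_solve.py`, …). A thin CLI covers the same
ground from a shell:

```bash
monogyny defaults                                   # print the parameter set
monogyny solve --set sex_ratio=2 --out runs/r2      # one equilibrium, CSV tables
monogyny sweep --param sex_ratio=0.5,1,2 --out runs/sweep
```

## Validation

Two independent routes check the deterministic pipeline: an exhaustive
best-response search on one-step seasons must reproduce the
backward-induction argmax, and a finite-population agent-based simulation
(explicit spiders, sites, sampled copulations, realized raffle paternity)
must match the mean-field class trajectories and the dynamic-programming
value within Monte-Carlo error (`examples/04_abm_validation.py`).

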