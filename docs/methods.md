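# Methods

This note documents the model as implemented: its assumptions, the
numerical machinery, the choices made where the biology leaves the design
open, and the limits of what the test suite demonstrates.

## Model structure

One mating season of `t_max` discrete steps (a step is the time a male
needs to move between web sites) over an infinite population, all masses
expressed relative to the initial number of subadult females (= 1).
Subadults moult to adulthood with sex-specific per-step probabilities;
with the defaults (`maturation_male = 1`, `maturation_female = 0.5`) all
males mature at the season's first step while females keep maturing — a
protandrous schedule. Both sexes face per-step mortality. Oviposition
happens at the end of the season.

**Male state** is `virgin` or `mated` (exactly one pedipalp used); a male
who has used both pedipalps cannot reproduce further and is dropped from
all bookkeeping. **Female state** is size (`small`/`large`, fixed for
life), the used/unused flags of her two genital openings, and stored sperm
in integer units. Males perceive only her size and whether she is a virgin,
so strategies condition on the observable class, while plug failure and the
raffle depend on the hidden detail.

**Decision situations.** A strategy assigns a distribution over attempted
copulation durations `c ∈ {0,…,10}` (0 = reject/leave) to each combination
of (male status, female status on arrival, female size, whether the focal
pair just mated this step, `t`). Biologically reachable combinations number
`12·t_max − 8`: at `t = 1` females have only just matured and all males
arrive simultaneously, so every first encounter is virgin-male ×
virgin-female (plus its just-mated follow-ups).

**Copulation mechanics.** The female attacks at a tick `T` uniform on
{1,…,10}; the male escapes at `c` if `T > c` (transferring exactly `c`
units, one per second), otherwise he dies, transferring `T + Δ` units
(`Δ = delta_extension`, default 10 — the male gains the extension even if
he had planned to escape later; the switch `delta_on_interrupted: false`
restricts the extension to committed `c = 10` copulations). This
discretization reproduces the linear survival law `P(survive|c) = 1 − c/10`
exactly while keeping sperm integer-valued. Copulating into a used opening
transfers nothing with probability `plug` (all-or-nothing), and marks the
opening used regardless. Insemination is ipsilateral, so an unrelated male
hits a half-plugged female's used side with probability ½, while a
same-pair second copulation is forced onto the complement of the first.

**Mate search.** Each step every searching male relocates; a site holding
an adult female is `a_virgin` or `a_mated` times as attractive as an empty
one. With site weight `W = (#empty) + Σ_j a_j f_j`, a male finds a class-j
female with probability `f_j a_j / W`, and a given female receives
Poisson-many male arrivals with intensity `λ_j = n_searching · a_j / W`
(truncated at `arrival_k_max`, tail mass folded into the top bin).

**Within-step interactions.** All arrivals at a female's site are treated
as simultaneous for *decisions* — each keys his situation to her class at
the start of the step — but sequential in uniformly random order for
*mechanics*: openings used by an earlier arrival raise later arrivals'
plug-failure odds and sperm accumulates. This is the only scheme we found
consistent with the `12·t_max − 8` reachability count (a sequential
*perceived* update would create "mated on arrival" situations at `t = 1`).
A virgin male who survives his first copulation immediately plays the
just-mated decision against the same female.

**Fitness.** Paternity is a fair raffle over sperm stored at oviposition,
weighted by the female's survival to season end and her fecundity
(large = 1, small = `fecundity_small`). A female with zero stored sperm
yields no offspring to anyone. Within a step the order of operations is
maturation → encounter → mating → mortality, identically in every module;
mortality is applied at the end of steps `1 … t_max − 1` only — the final
step's matings are immediately followed by oviposition, so no mortality
draw intervenes (this keeps the forward pass, the competition kernel and
the agent-based model mutually consistent).

## Forward pass and competition kernel

The season under a resident strategy is advanced as a deterministic
mean-field recursion on female masses indexed by (size, opening summary,
stored sperm 0…`sperm_cap`). The per-arrival effect of one resident male
(action mixture, side symmetry, plug lottery, possible same-female second
copulation) is assembled once per (size, class, t) as an operator on
(openings, sperm-gained); compounding it over the truncated-Poisson arrival
count gives the step's mating transition. Male pools update from the same
per-arrival action statistics, which conserves the male/female sides of the
mating market exactly. When more females are alive than sites (`S < 1`),
maturation is deferred until a site frees up (a queue); this regime is not
pinned down by the biology and the queue is this package's design choice.

The **competition kernel** `K[s, t]` gives, for a female left in detailed
state `s` at the end of step `t`'s matings, the joint distribution of the
additional competing sperm she will receive in later steps and her survival
to oviposition (total mass = survival probability). It is computed by a
backward recursion over the same per-step mating transitions, for *every*
detailed state — including states only a mutant could create.

## Backward dynamic programming

`V[status, t]` is the expected number of offspring from step `t` onward:

```
V[status, t] = Σ_j find_j · W[status, j, t]
             + (1 − Σ_j find_j) · (1 − mortality_male) · V[status, t+1]
```

with `V[·, t_max+1] = 0` and `W` the smoothed-average action value on
meeting class j. Action values combine the immediate expected raffle gain
with survival-weighted continuations; a mated male's copulation uses his
last pedipalp, so his continuation after mating is zero — which makes
`c = 10` (no escape attempt) optimal in every mated-male situation whose
best action is to mate at all.

**Same-step rivals.** A focal male's gain evaluation enumerates his
position among the step's arrivals exactly: with `k ∼ TruncPoisson(λ_j)`
rivals and a uniform position, `n_before` rivals first evolve the female's
hidden (openings, sperm) state with the same one-arrival operator as the
forward pass, and `n_after` rivals act on her post-copulation state before
the between-step kernel takes over. Without this term, paternity at
`t_max` would saturate at 1 for any positive transfer and the model would
lose its terminal behavior (universal second copulations in the final
step); with it, mutant valuation and resident dynamics describe the same
market.

**Second copulations and the strategy's information set.** The value of
the just-mated decision depends on how much sperm the male transferred in
his first copulation, which is not part of the situation. Its action
values are averaged over the reach distribution of (first duration,
survival, plug outcome) induced by the *resident's* first-copulation row;
the focal male's own first-copulation values then use his new smoothed
just-mated row as continuation. At a fixed point the two coincide.

**Error smoothing.** Action weights are
`exp(−(V* − Q(c)) / (δ · max(V*, ε)))`, normalized — a logit rule on the
*relative* value shortfall, so that δ is dimensionless and costlier errors
are rarer; `δ = 0.1` by default, `error_absolute_scale: true` switches to
an absolute-shortfall scale. δ → 0 recovers the pure argmax (ties broken
toward the smallest `c`).

**ESS loop.** Starting from a uniform resident, each cycle derives the
resident's environment, computes the smoothed best response, and blends it
into the resident with damping 0.5; convergence is a sup-norm gap below
`1e-6` over all action probabilities, reached in ~25 iterations at the
defaults (~20 s on one CPU). The pipeline is fully deterministic. Solves
from different initial strategies reach the same equilibrium within
numerical tolerance at the defaults; non-convergence is reported, never
silent.

## Parameters

| name | meaning | default | units |
|---|---|---|---|
| `plug` | transfer failure into a used opening | 0.8 | probability |
| `maturation_male/female` | per-step moult probability | 1 / 0.5 | probability |
| `mortality_male/female` | per-step death probability | 0.02 / 0.02 | probability |
| `delta_extension` | post-attack copulation extension | 10 | s (= sperm units) |
| `sex_ratio` | initial males per female | 1 | — |
| `sites_per_female` | web sites per initial female | 1 | — |
| `attract_virgin/mated` | site attractiveness vs empty | 5 / 1 | — |
| `prop_large` | share of large females | 0.5 | — |
| `fecundity_small` | small-female relative fecundity | 0.5 | — |
| `t_max` | steps per season | 10 | — |
| `error_delta` | decision-error coefficient | 0.1 | — |

Solver controls: `convergence_tol = 1e-6`, `max_iterations = 500`,
`damping = 0.5`, `sperm_cap = 100` (saturating addition; tail mass is
negligible at the defaults), `arrival_k_max = 7`. The truncation default
was set by a convergence study: with `k_max = 3` the arrival intensities
reached when few females are adult (λ ≈ 2.5) lose ~1–2% tail mass, shifting
season aggregates by ~0.02 and distorting the maturation-rate trend; beyond
`k_max = 7` aggregates change by < 10⁻³.

## Validation

* **Exhaustive oracle.** For one-step seasons, every pure strategy is
  evaluated by an independently coded direct expectation (dictionary-based
  enumeration over rival sequences and copulation outcomes); its optimal
  actions match the backward-induction argmax in the near-pure limit
  (δ = 10⁻⁶).
* **Agent-based model.** Explicit individuals and sites, sampled outcomes,
  realized raffle paternity. At 10⁵ initial females its per-step class
  frequencies match the mean-field trajectories within 3 binomial standard
  errors, and its mean male fitness matches `V[virgin, 1]`.
* **Single-mutant rollout.** A Monte-Carlo rollout of one focal male in
  the frozen equilibrium environment (sampling rival positions, hidden
  female states and the kernel) reproduces the dynamic-programming value.

The agent-based model emulates the same idealized season — exchangeable
sites, memoryless relocation, uniform female behavior, two size classes,
all-or-nothing plugs. Passing tests therefore demonstrate internal
consistency of the deterministic and stochastic formulations, not fidelity
to field data: real *A. bruennichi* males lose legs, females vary in
aggression, and size is continuous.

## Known limitations and open edges

* **Density below one site per female.** For `S < 1` the deferred-
  maturation queue (our reconstruction) makes the operational sex ratio
  male-biased early in the season, which favors monogyny strongly enough to
  reverse the otherwise positive effect of density on bigyny observed for
  `S ≥ 1` (aggregated bigyny 0.49 / 0.57 / 0.38 at S = 4 / 1 / 0.5). The
  behavior of the model in this regime depends on that design choice.
* **Smoothed acceptance near ties.** On virgin-female classes, where both
  male types essentially always mate, the error-smoothed acceptance of
  mated males can exceed that of virgin males by a few percent (their
  outside option is worse, so rejection carries a larger relative
  shortfall). The choosiness ordering holds per mated-female class, in the
  encounter-weighted aggregate, and under the pure argmax.
* **Perception within a step** uses the start-of-step class (see above);
  a female mated earlier in the same step is still treated as a virgin by
  that step's later arrivals, though her openings and sperm are current.
* The mutant's hidden-state conditioning uses the resident-induced
  distribution per observable class; out-of-equilibrium strategies far from
  the resident are valued against that resident's environment, as the game
  requires.

## Problem sizes used by the tests and the acceptance script

The default parameter set (above) is used throughout: one equilibrium
solve per directional grid point (3-point sweeps for sex ratio, female
maturation and density; a 2×2 grid for the female-quality surface), an
agent-based season at 10⁵ initial females (single replicate, fixed seed)
plus smaller replicated runs, 2×10⁴ single-mutant rollouts, and 10⁵
simulated copulations for the plug-failure recovery. The exhaustive oracle
runs at `t_max = 1` with `arrival_k_max = 2`.
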