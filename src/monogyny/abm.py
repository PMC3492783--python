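"""Independent validators of the mean-field machinery.

Three routes:

* :func:`simulate_abm` — a finite-population agent-based simulation of the
  same season (explicit males, females and sites, sampled copulation
  outcomes, realized fair-raffle paternity at oviposition).  For large
  populations its class frequencies and mean male fitness converge to the
  deterministic recursions and the dynamic-programming value.
* :func:`mutant_value_mc` — Monte-Carlo rollout of a single focal male
  following a given strategy inside a frozen resident environment,
  sampling rivals, hidden female states and the competition kernel; its
  mean payoff estimates V[virgin, 1] computed by backward induction.
* :func:`exhaustive_best_response` — for single-step seasons, enumerate
  all pure strategies and evaluate each by direct expectation; the argmax
  must agree with the backward-induction argmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelParameters
from .encounter import arrival_distribution
from .forward import SIZES, SeasonEnvironment
from .mating import outcome_distribution
from .states import MATED, VIRGIN, FemaleClass, Situation, Strategy

__all__ = ["ABMConfig", "ABMResult", "simulate_abm", "mutant_value_mc", "exhaustive_best_response"]


@dataclass(frozen=True)
class ABMConfig:
    n_initial_females: int = 10_000
    seed: int = 0
    replicates: int = 3

    def __post_init__(self):
        if self.n_initial_females < 1 or self.replicates < 1:
            raise ValueError("n_initial_females and replicates must be >= 1")


@dataclass
class ABMResult:
    """Replicate-averaged tables with Monte-Carlo standard errors."""

    #: columns: t, female_size, female_status, frequency, se
    class_frequencies: pd.DataFrame
    #: columns: male_status, female_status, female_size, t, decisions,
    #: matings, monogyny1, monogyny2, bigyny (counts, replicate means)
    outcomes: pd.DataFrame
    male_mean_fitness: float
    male_fitness_se: float
    replicates: int
    n_initial_females: int


def _sample(cum: np.ndarray, u: float) -> int:
    return int(np.searchsorted(cum, u, side="right"))


def simulate_abm(params: ModelParameters, strategy: Strategy, abm: ABMConfig) -> ABMResult:
    """Finite-population stochastic season(s) under a fixed strategy.

    Site choice is pheromone-weighted, same-site arrivals interact with the
    female in uniformly random order (decisions keyed to her start-of-step
    status, mechanics to her current openings), and paternity is a realized
    fair raffle among the sperm stored by each surviving female at season
    end.  Deterministic under a fixed seed.
    """
    freq_frames = []
    out_frames = []
    fitness = []
    for r in range(abm.replicates):
        rng = np.random.default_rng([abm.seed, r])
        f, o, fit = _replicate(params, strategy, rng, abm.n_initial_females)
        freq_frames.append(f)
        out_frames.append(o)
        fitness.append(fit)
    freq = pd.concat(freq_frames)
    keys = ["t", "female_size", "female_status"]
    g = freq.groupby(keys)["frequency"]
    n = abm.n_initial_females
    cf = g.mean().reset_index()
    # binomial standard error of a class frequency at the replicate scale
    cf["se"] = np.sqrt(np.maximum(cf["frequency"] * (1 - cf["frequency"]), 1e-12) / (n * abm.replicates))
    out = (
        pd.concat(out_frames)
        .groupby(["male_status", "female_status", "female_size", "t"], as_index=False)
        .mean()
    )
    fit_arr = np.asarray(fitness)
    se = fit_arr.std(ddof=1) / np.sqrt(abm.replicates) if abm.replicates > 1 else np.nan
    return ABMResult(
        class_frequencies=cf,
        outcomes=out,
        male_mean_fitness=float(fit_arr.mean()),
        male_fitness_se=float(se),
        replicates=abm.replicates,
        n_initial_females=abm.n_initial_females,
    )


def _replicate(params: ModelParameters, strategy: Strategy, rng: np.random.Generator, n_f: int):
    p = params
    n_m = int(round(p.sex_ratio * n_f))
    n_sites = int(round(p.sites_per_female * n_f))
    delta = int(p.delta_extension)

    cum = {sit: np.cumsum(strategy.distribution(sit)) for sit in strategy.situations}

    f_large = rng.random(n_f) < p.prop_large
    f_adult = np.zeros(n_f, bool)
    f_alive = np.ones(n_f, bool)
    f_used = np.zeros((n_f, 2), bool)  # left/right opening used
    m_adult = np.zeros(n_m, bool)
    m_alive = np.ones(n_m, bool)
    m_virgin = np.ones(n_m, bool)
    m_active = np.ones(n_m, bool)  # not yet retired (fewer than two palps used)

    contrib: dict[int, dict[int, int]] = {}
    freq_rows = []
    out_counts: dict[tuple, np.ndarray] = {}

    def tally(ms, fstat, size, t, kind):
        key = (ms, fstat, size, t)
        if key not in out_counts:
            out_counts[key] = np.zeros(5)
        idx = {"decisions": 0, "matings": 1, "monogyny1": 2, "monogyny2": 3, "bigyny": 4}[kind]
        out_counts[key][idx] += 1

    def copulate(f, male, c, side, t):
        """One copulation; returns (male survived, sperm recorded)."""
        used = f_used[f, side]
        attack = rng.integers(1, 11)
        survived = attack > c
        raw = c if survived else attack + (delta if (p.delta_on_interrupted or c == 10) else 0)
        sperm = 0 if (used and rng.random() < p.plug) else raw
        f_used[f, side] = True
        if sperm > 0:
            contrib.setdefault(f, {})
            contrib[f][male] = contrib[f].get(male, 0) + sperm
        return survived

    for t in range(1, p.t_max + 1):
        # maturation
        sub_m = m_alive & ~m_adult
        m_adult[sub_m & (rng.random(n_m) < p.maturation_male)] = True
        cand = np.flatnonzero(f_alive & ~f_adult & (rng.random(n_f) < p.maturation_female))
        slots = n_sites - int((f_alive & f_adult).sum())
        if cand.size > slots:
            cand = rng.choice(cand, size=max(slots, 0), replace=False)
        f_adult[cand] = True

        # class-frequency snapshot (post-maturation, pre-mating)
        fem = np.flatnonzero(f_alive & f_adult)
        fem_virgin = ~f_used[fem].any(axis=1)
        for size_flag, size in ((False, SIZES[0]), (True, SIZES[1])):
            sel = f_large[fem] == size_flag
            freq_rows.append(dict(t=t, female_size=size, female_status=VIRGIN,
                                  frequency=(sel & fem_virgin).sum() / n_f))
            freq_rows.append(dict(t=t, female_size=size, female_status=MATED,
                                  frequency=(sel & ~fem_virgin).sum() / n_f))

        # search: each male picks a site; occupied sites are weighted
        searchers = np.flatnonzero(m_alive & m_adult & m_active)
        if searchers.size and fem.size:
            w = np.where(fem_virgin, p.attract_virgin, p.attract_mated).astype(float)
            n_empty = max(n_sites - fem.size, 0)
            probs = np.append(w, n_empty) / (w.sum() + n_empty)
            choice = rng.choice(fem.size + 1, size=searchers.size, p=probs)
            order = rng.permutation(searchers.size)
            start_virgin = fem_virgin.copy()
            by_female: dict[int, list[int]] = {}
            for k in order:
                if choice[k] < fem.size:
                    by_female.setdefault(int(choice[k]), []).append(int(searchers[k]))
            for fi, males in by_female.items():
                f = int(fem[fi])
                fstat = VIRGIN if start_virgin[fi] else MATED
                size = SIZES[1] if f_large[f] else SIZES[0]
                for male in males:
                    ms = VIRGIN if m_virgin[male] else MATED
                    sit = Situation(ms, fstat, size, False, t)
                    c = _sample(cum[sit], rng.random())
                    tally(ms, fstat, size, t, "decisions")
                    if c == 0:
                        continue
                    tally(ms, fstat, size, t, "matings")
                    side = int(rng.integers(2))
                    survived = copulate(f, male, c, side, t)
                    if ms == MATED:
                        m_active[male] = False
                        if not survived:
                            m_alive[male] = False
                        continue
                    if not survived:
                        m_alive[male] = False
                        tally(ms, fstat, size, t, "monogyny1")
                        continue
                    m_virgin[male] = False
                    sit2 = Situation(MATED, fstat, size, True, t)
                    c2 = _sample(cum[sit2], rng.random())
                    if c2 == 0:
                        tally(ms, fstat, size, t, "bigyny")
                        continue
                    tally(ms, fstat, size, t, "monogyny2")
                    survived2 = copulate(f, male, c2, 1 - side, t)
                    m_active[male] = False
                    if not survived2:
                        m_alive[male] = False

        # mortality (season ends right after the final matings)
        if t < p.t_max:
            m_alive &= rng.random(n_m) >= p.mortality_male
            f_alive &= rng.random(n_f) >= p.mortality_female

    # oviposition: realized fair raffle per surviving female
    fitness = np.zeros(n_m)
    for f, shares in contrib.items():
        if not f_alive[f]:
            continue
        total = sum(shares.values())
        fec = 1.0 if f_large[f] else p.fecundity_small
        for male, x in shares.items():
            fitness[male] += fec * x / total
    out = pd.DataFrame(
        [
            dict(male_status=k[0], female_status=k[1], female_size=k[2], t=k[3],
                 decisions=v[0], matings=v[1], monogyny1=v[2], monogyny2=v[3], bigyny=v[4])
            for k, v in out_counts.items()
        ]
    )
    return pd.DataFrame(freq_rows), out, float(fitness.sum() / n_m)


def mutant_value_mc(
    env: SeasonEnvironment, strategy: Strategy, n: int = 50_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo estimate of V[virgin, 1] for a focal male following
    ``strategy`` in the frozen resident environment.

    Samples, per encounter: the focal male's position among the step's
    truncated-Poisson arrivals, the rival interactions before and after him
    (resident actions, copulation outcomes), the female's hidden start-of-
    step state, and finally her future competition and survival from the
    kernel.  Returns (mean payoff, standard error).
    """
    params = env.params
    p = params
    rng = np.random.default_rng(seed)
    k_max = p.solver.arrival_k_max
    delta = int(p.delta_extension)
    cum_mut = {sit: np.cumsum(strategy.distribution(sit)) for sit in strategy.situations}
    cum_res = {sit: np.cumsum(env.resident.distribution(sit)) for sit in env.resident.situations}

    def draw_copulation(c, used):
        attack = rng.integers(1, 11)
        survived = attack > c
        raw = c if survived else attack + (delta if (p.delta_on_interrupted or c == 10) else 0)
        sperm = 0 if (used and rng.random() < p.plug) else raw
        return survived, sperm

    def rival_interaction(openings, fstat, size, t, rec):
        """One resident rival: returns (new opening flags, sperm added)."""
        ms = VIRGIN if rng.random() < rec.p_virgin_male else MATED
        sit = Situation(ms, fstat, size, False, t)
        c = _sample(cum_res[sit], rng.random()) if sit in cum_res else 0
        if c == 0:
            return openings, 0
        side = int(rng.integers(2))
        survived, sperm = draw_copulation(c, openings[side])
        openings = list(openings)
        openings[side] = True
        if ms == VIRGIN and survived:
            sit2 = Situation(MATED, fstat, size, True, t)
            c2 = _sample(cum_res[sit2], rng.random()) if sit2 in cum_res else 0
            if c2 > 0:
                _, sperm2 = draw_copulation(c2, openings[1 - side])
                openings[1 - side] = True
                sperm += sperm2
        return tuple(openings), sperm

    payoffs = np.empty(n)
    for sim in range(n):
        status = VIRGIN
        payoff = 0.0
        t = 1
        while t <= p.t_max:
            rec = env.record(t)
            u = rng.random()
            acc = 0.0
            found = None
            for j, fj in rec.rates.find.items():
                acc += fj
                if u < acc:
                    found = j
                    break
            if found is not None:
                size = found.size
                i = SIZES.index(size)
                fstat = found.status
                # hidden start-of-step state
                D = rec.D
                if fstat == VIRGIN:
                    openings, y0 = (False, False), 0
                else:
                    col = D[i, 1:].ravel()
                    tot = col.sum()
                    if tot < 1e-300:
                        openings, y0 = (True, False), 0
                    else:
                        idx = _sample(np.cumsum(col) / tot, rng.random())
                        o, y0 = divmod(idx, D.shape[2])
                        openings = (True, o == 1)  # o=0 -> half, o=1 -> full
                        if rng.random() < 0.5:
                            openings = (openings[1], openings[0])
                # rivals this step and focal position
                lam = rec.lam_by_status[fstat] if rec.SA is not None else 0.0
                pk = arrival_distribution(lam, k_max)
                k = _sample(np.cumsum(pk), rng.random())
                pos = int(rng.integers(k + 1))
                for _ in range(pos):
                    openings, add = rival_interaction(openings, fstat, size, t, rec)
                    y0 += add
                sit = Situation(status, fstat, size, False, t)
                c = _sample(cum_mut[sit], rng.random())
                if c > 0:
                    side = int(rng.integers(2))
                    survived, x = draw_copulation(c, openings[side])
                    openings = list(openings)
                    openings[side] = True
                    openings = tuple(openings)
                    done = status == MATED
                    if status == VIRGIN and survived:
                        status = MATED
                        sit2 = Situation(MATED, fstat, size, True, t)
                        c2 = _sample(cum_mut[sit2], rng.random())
                        if c2 > 0:
                            _, x2 = draw_copulation(c2, openings[1 - side])
                            openings = (True, True)
                            x += x2
                            done = True
                    if x > 0:
                        comp = y0
                        for _ in range(k - pos):
                            openings, add = rival_interaction(openings, fstat, size, t, rec)
                            comp += add
                        o_end = int(openings[0]) + int(openings[1])
                        K = env.kernel[t, i, o_end]
                        mass = K.sum()
                        if rng.random() < mass:  # she survives to oviposition
                            y_fut = _sample(np.cumsum(K) / mass, rng.random())
                            fec = 1.0 if size == SIZES[1] else p.fecundity_small
                            payoff += fec * x / (x + comp + y_fut)
                    if not survived or done:
                        break
            # between-step male mortality
            if rng.random() < p.mortality_male:
                break
            t += 1
        payoffs[sim] = payoff
    return float(payoffs.mean()), float(payoffs.std(ddof=1) / np.sqrt(n))


def _rival_effect(params: ModelParameters, env: SeasonEnvironment, size: str, fstat: str, t: int):
    """Distribution of one rival's effect on the female, per mechanical
    opening count (0/1/2 sides used): dict (used_after, sperm_added) -> prob.
    Built from the public single-copulation primitives (independent of the
    vectorized forward-pass operator)."""
    rec = env.record(t)
    shares = {VIRGIN: rec.p_virgin_male, MATED: rec.p_mated_male}
    effects = []
    for o in range(3):
        eff: dict[tuple[int, int], float] = {}

        def add(key, pr):
            eff[key] = eff.get(key, 0.0) + pr

        sides = {0: [(1.0, 0, 0)], 1: [(0.5, 1, 0), (0.5, 0, 1)], 2: [(1.0, 1, 1)]}[o]
        for ms, w_ms in shares.items():
            if w_ms <= 0:
                continue
            sit = Situation(ms, fstat, size, False, t)
            try:
                row = env.resident.distribution(sit)
            except KeyError:
                add((o, 0), w_ms)
                continue
            add((o, 0), w_ms * row[0])
            for c in range(1, 11):
                if row[c] <= 0:
                    continue
                for sp, u1, u2 in sides:
                    o1 = o + (1 - u1)
                    for out, pr in outcome_distribution(c, bool(u1), params).items:
                        base = w_ms * row[c] * sp * pr
                        if ms == MATED or not out.survived:
                            add((o1, out.sperm_transferred), base)
                            continue
                        sit2 = Situation(MATED, fstat, size, True, t)
                        row2 = env.resident.distribution(sit2)
                        add((o1, out.sperm_transferred), base * row2[0])
                        for c2 in range(1, 11):
                            if row2[c2] <= 0:
                                continue
                            for out2, pr2 in outcome_distribution(c2, bool(u2), params).items:
                                add(
                                    (2, out.sperm_transferred + out2.sperm_transferred),
                                    base * row2[c2] * pr2,
                                )
        effects.append(eff)
    return effects


def _evolve(dist: dict, effects, steps: int) -> dict:
    for _ in range(steps):
        nxt: dict[tuple[int, int], float] = {}
        for (o, y), pr in dist.items():
            for (o1, dy), pe in effects[o].items():
                key = (o1, y + dy)
                nxt[key] = nxt.get(key, 0.0) + pr * pe
        dist = nxt
    return dist


def exhaustive_best_response(env: SeasonEnvironment) -> dict[Situation, set[int]]:
    """Enumerate every pure strategy of a one-step season and evaluate each
    by direct expectation in the frozen environment; returns, per situation,
    the set of optimal actions (ties within 1e-12).

    Only t_max = 1 is accepted (11^4 pure strategies); longer seasons are
    refused as combinatorially infeasible.
    """
    params = env.params
    if params.t_max != 1:
        raise ValueError("exhaustive search is limited to t_max = 1 seasons")
    rec = env.record(1)
    k_max = params.solver.arrival_k_max
    lam = rec.lam_by_status[VIRGIN] if rec.SA is not None else 0.0
    pk = arrival_distribution(lam, k_max)
    pairs: dict[tuple[int, int], float] = {}
    for k in range(k_max + 1):
        for b in range(k + 1):
            pairs[(b, k - b)] = pairs.get((b, k - b), 0.0) + pk[k] / (k + 1)

    # value tables per size: val[size][(c1, c2)]
    od = {
        (c, u): outcome_distribution(c, bool(u), params).items
        for c in range(11)
        for u in (0, 1)
    }
    val: dict[str, np.ndarray] = {}
    for size in SIZES:
        fec = 1.0 if size == SIZES[1] else params.fecundity_small
        effects = _rival_effect(params, env, size, VIRGIN, 1)
        table = np.zeros((11, 11))
        after_cache: dict[tuple[int, int], dict] = {}
        gain_cache: dict[tuple[int, int, int, int], float] = {}

        def gain(x, o_after, y0, a):
            if x == 0:
                return 0.0
            key = (x, o_after, y0, a)
            if key in gain_cache:
                return gain_cache[key]
            if (o_after, a) not in after_cache:
                after_cache[(o_after, a)] = _evolve({(o_after, 0): 1.0}, effects, a)
            g = 0.0
            for (_oe, dy), pr in after_cache[(o_after, a)].items():
                g += pr * x / (x + y0 + dy)
            g *= fec
            gain_cache[key] = g
            return g

        for (b, a), q in pairs.items():
            H = _evolve({(0, 0): 1.0}, effects, b)
            for (o, y0), ph in H.items():
                sides = {0: [(1.0, 0, 0)], 1: [(0.5, 1, 0), (0.5, 0, 1)], 2: [(1.0, 1, 1)]}[o]
                for c1 in range(1, 11):
                    for sp, u1, u2 in sides:
                        o1 = o + (1 - u1)
                        for out, pr in od[(c1, u1)]:
                            w = q * ph * sp * pr
                            if not out.survived:
                                table[c1, :] += w * gain(out.sperm_transferred, o1, y0, a)
                            else:
                                x1 = out.sperm_transferred
                                table[c1, 0] += w * gain(x1, o1, y0, a)
                                for c2 in range(1, 11):
                                    g2 = 0.0
                                    for out2, pr2 in od[(c2, u2)]:
                                        g2 += pr2 * gain(x1 + out2.sperm_transferred, 2, y0, a)
                                    table[c1, c2] += w * g2
        val[size] = table

    find = {j: f for j, f in rec.rates.find.items() if f > 0}
    best_value = -np.inf
    best_combo = None
    for c1s in range(11):
        for c2s in range(11):
            for c1l in range(11):
                for c2l in range(11):
                    v = find.get(FemaleClass(SIZES[0], VIRGIN), 0.0) * val[SIZES[0]][c1s, c2s] + (
                        find.get(FemaleClass(SIZES[1], VIRGIN), 0.0) * val[SIZES[1]][c1l, c2l]
                    )
                    if v > best_value:
                        best_value = v
                        best_combo = (c1s, c2s, c1l, c2l)
    # optimal-action sets per situation from the per-size tables; if a size
    # class is never found, every action ties at zero total value
    out: dict[Situation, set[int]] = {}
    for size in SIZES:
        if find.get(FemaleClass(size, VIRGIN), 0.0) <= 0.0:
            out[Situation(VIRGIN, VIRGIN, size, False, 1)] = set(range(11))
            out[Situation(MATED, VIRGIN, size, True, 1)] = set(range(11))
            continue
        table = val[size]
        c1_best = table.max(axis=1)
        top = c1_best.max()
        out[Situation(VIRGIN, VIRGIN, size, False, 1)] = {
            c for c in range(11) if c1_best[c] >= top - 1e-12
        }
        c1_star = int(np.argmax(c1_best))
        row = table[c1_star]
        out[Situation(MATED, VIRGIN, size, True, 1)] = {
            c for c in range(11) if row[c] >= row.max() - 1e-12
        }
    assert best_combo is not None
    return out
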