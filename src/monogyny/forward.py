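"""Deterministic mean-field forward pass of one mating season under a
resident strategy, and the forward-looking sperm-competition kernel.

All masses are expressed relative to the initial number of subadult
females (set to 1).  Within each time step the order of operations is:
maturation -> encounter -> mating -> mortality.  Mortality is applied at
the end of steps 1..t_max-1; after the final step's matings the season
ends and females oviposit, so no further mortality draw intervenes.

Within a step, all arriving males see the female's class as it was at the
start of the step (they arrive simultaneously), but interact with her in
sequence: openings already used earlier in the step raise the later
arrivals' plug-failure odds and sperm accumulates.  The number of arrivals
at one female's site is Poisson with the class-specific intensity,
truncated at ``arrival_k_max``.

Stored sperm lives on an integer grid 0..sperm_cap with saturating
addition at the cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ModelParameters
from .encounter import EncounterRates, arrival_distribution, encounter_rates
from .mating import sperm_distributions
from .states import (
    LARGE,
    MATED,
    SMALL,
    VIRGIN,
    FemaleClass,
    Situation,
    Strategy,
    enumerate_situations,
)

__all__ = [
    "SIZES",
    "PopulationState",
    "StepRecord",
    "Season",
    "SeasonEnvironment",
    "step_subadults",
    "step_population",
    "run_season",
    "competition_kernel",
    "build_environment",
]

SIZES = (SMALL, LARGE)

#: opening-summary indices: 0 = virgin, 1 = half-plugged, 2 = fully plugged
N_OPEN = 3

# Side-resolution branches per mechanical opening state of the female at the
# male's turn: (probability, first-cop hits used side, opening after first
# cop, second-cop side is used).  After a same-pair second copulation both
# openings are always used (index 2).
_BRANCHES = {
    0: [(1.0, 0, 1, 0)],
    1: [(0.5, 1, 1, 0), (0.5, 0, 2, 1)],
    2: [(1.0, 1, 2, 1)],
}


def step_subadults(p: float, maturation: float, mortality: float) -> tuple[float, float]:
    """One step of the subadult pool: maturation first, then mortality.

    Returns ``(remaining subadult mass, newly adult mass)`` =
    ``(p*(1-maturation)*(1-mortality), p*maturation)``.
    """
    if p < 0:
        raise ValueError("negative subadult mass")
    new_adults = p * maturation
    remaining = (p - new_adults) * (1.0 - mortality)
    return remaining, new_adults


def _conv_sat(a: np.ndarray, b: np.ndarray, cap: int) -> np.ndarray:
    """Convolution on the sperm grid with tail mass folded into the cap bin."""
    full = np.convolve(a, b)
    if full.size <= cap + 1:
        out = np.zeros(cap + 1)
        out[: full.size] = full
        return out
    out = full[: cap + 1].copy()
    out[cap] += full[cap + 1 :].sum()
    return out


@dataclass
class PopulationState:
    """Masses of every tracked class at one instant.

    ``females[size, openings, y]`` holds adult-female mass jointly with
    stored sperm y; size index 0 = small, 1 = large; openings index 0/1/2 =
    virgin/half/fully plugged.
    """

    subadult_females: float
    subadult_males: float
    males_virgin: float
    males_mated: float
    females: np.ndarray  # [2, 3, sperm_cap + 1]

    def check(self) -> "PopulationState":
        if (
            min(self.subadult_females, self.subadult_males, self.males_virgin, self.males_mated)
            < -1e-9
            or self.females.min() < -1e-9
        ):
            raise RuntimeError("negative population mass: internal bookkeeping bug")
        np.clip(self.females, 0.0, None, out=self.females)
        return self

    def class_masses(self) -> dict[FemaleClass, float]:
        out = {}
        for i, size in enumerate(SIZES):
            out[FemaleClass(size, VIRGIN)] = float(self.females[i, 0].sum())
            out[FemaleClass(size, MATED)] = float(self.females[i, 1:].sum())
        return out

    def total_adult_females(self) -> float:
        return float(self.females.sum())

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.subadult_females,
            self.subadult_males,
            self.males_virgin,
            self.males_mated,
            self.females.copy(),
        )

    @classmethod
    def initial(cls, params: ModelParameters) -> "PopulationState":
        cap = params.solver.sperm_cap
        return cls(1.0, params.sex_ratio, 0.0, 0.0, np.zeros((2, N_OPEN, cap + 1)))


@dataclass
class StepRecord:
    """Everything the backward pass needs about one forward step."""

    t: int
    rates: EncounterRates
    #: female state distribution after maturation, before mating: [2, 3, cap+1]
    D: np.ndarray
    #: compound mating transition M[size, o_start, o_end, sperm_added]
    M: np.ndarray
    #: one-arrival operator SA[size, status, o, o', sperm_added] (None if no
    #: males search this step); status 0 = virgin class, 1 = mated class
    SA: np.ndarray | None
    #: per-female arrival intensity by female status {VIRGIN: .., MATED: ..}
    lam_by_status: dict[str, float]
    #: expected male arrivals per class over the whole step
    arrivals: dict[FemaleClass, float]
    #: share of searching males that are virgin / mated
    p_virgin_male: float
    p_mated_male: float
    #: expected sperm units added to females this step (from M)
    sperm_added: float


@dataclass
class Season:
    """Result of one forward pass: per-step records and state trajectory."""

    params: ModelParameters
    resident: Strategy
    records: list[StepRecord]
    #: trajectory[t] is the state at the END of step t; trajectory[0] is initial
    trajectory: list[PopulationState]

    def record(self, t: int) -> StepRecord:
        return self.records[t - 1]


@dataclass
class SeasonEnvironment:
    """Frozen resident-generated environment a mutant male optimizes against."""

    params: ModelParameters
    resident: Strategy
    season: Season
    #: kernel[t][size, openings, y]: distribution of future competing sperm
    #: jointly with survival-to-oviposition, for a female in the given state
    #: at the end of step t's mating phase; defined for t = 1..t_max
    kernel: np.ndarray  # [t_max + 1, 2, 3, cap + 1]

    def record(self, t: int) -> StepRecord:
        return self.season.record(t)


def _single_arrival_operator(
    J: np.ndarray,
    sigma_v: np.ndarray,
    sigma_m: np.ndarray,
    sigma_jm: np.ndarray,
    p_virgin: float,
    p_mated: float,
) -> np.ndarray:
    """Effect of one arriving resident male on the female.

    Returns ``SA[o, o', dy]``: the female moves from mechanical opening
    state o to o' gaining dy sperm units.  ``J[used, survived, c, s]`` comes
    from :func:`monogyny.mating.sperm_distributions`; the sigma rows are the
    resident's action distributions for this (female class, size, t).
    """
    n_s = J.shape[3]  # 11 + delta
    L = 2 * (n_s - 1) + 1
    SA = np.zeros((N_OPEN, N_OPEN, L))

    # per used-flag mixtures over c > 0
    m_any = np.einsum("c,ucs->us", sigma_m[1:], J[:, 0, 1:, :] + J[:, 1, 1:, :])
    v_kill = np.einsum("c,ucs->us", sigma_v[1:], J[:, 0, 1:, :])
    v_surv = np.einsum("c,ucs->us", sigma_v[1:], J[:, 1, 1:, :])
    jm_any = np.einsum("c,ucs->us", sigma_jm[1:], J[:, 0, 1:, :] + J[:, 1, 1:, :])

    w_no_cop = p_virgin * sigma_v[0] + p_mated * sigma_m[0]
    for o in range(N_OPEN):
        SA[o, o, 0] += w_no_cop
        for hb, u1, o1, u2 in _BRANCHES[o]:
            # mated male: single copulation, female gains its sperm
            SA[o, o1, :n_s] += p_mated * hb * m_any[u1]
            # virgin male killed during the first copulation
            SA[o, o1, :n_s] += p_virgin * hb * v_kill[u1]
            # virgin male survives, then the just-mated decision
            SA[o, o1, :n_s] += p_virgin * hb * sigma_jm[0] * v_surv[u1]
            go = np.convolve(v_surv[u1], jm_any[u2])
            SA[o, 2, : go.size] += p_virgin * hb * go
    return SA


def step_population(
    pop: PopulationState, resident: Strategy, params: ModelParameters, t: int
) -> tuple[PopulationState, StepRecord]:
    """Advance the population through one time step under the resident.

    Returns the end-of-step state and the step record consumed by the
    backward pass.  Mortality is skipped in the final step (oviposition
    follows the final matings immediately).
    """
    cap = params.solver.sperm_cap
    k_max = params.solver.arrival_k_max
    pop = pop.copy()

    # -- maturation ---------------------------------------------------------
    new_adult_males = pop.subadult_males * params.maturation_male
    pop.subadult_males -= new_adult_males
    pop.males_virgin += new_adult_males

    empty_sites = max(params.sites_per_female - pop.total_adult_females(), 0.0)
    desired = pop.subadult_females * params.maturation_female
    matured = min(desired, empty_sites)  # surplus defers maturation (queued)
    pop.subadult_females -= matured
    pop.females[0, 0, 0] += matured * (1.0 - params.prop_large)
    pop.females[1, 0, 0] += matured * params.prop_large

    # -- encounter ----------------------------------------------------------
    counts = pop.class_masses()
    n_search = pop.males_virgin + pop.males_mated
    rates = encounter_rates(counts, n_search, params)
    D = pop.females.copy()

    # -- mating -------------------------------------------------------------
    J = sperm_distributions(params)
    L2 = 2 * (J.shape[3] - 1)
    Lm = k_max * L2 + 1
    M = np.zeros((2, N_OPEN, N_OPEN, Lm))
    arrivals: dict[FemaleClass, float] = {j: 0.0 for j in counts}
    p_v = pop.males_virgin / n_search if n_search > 0 else 0.0
    p_m = pop.males_mated / n_search if n_search > 0 else 0.0

    _reject = np.zeros(11)
    _reject[0] = 1.0
    reachable = set(enumerate_situations(params.t_max))

    def sigma(ms: str, fstat: str, size: str, jm: bool, weight: float = 1.0) -> np.ndarray:
        """Resident row; unreachable situations (mated males or mated
        females at t = 1) carry no mass and map to pure rejection."""
        sit = Situation(ms, fstat, size, jm, t)
        if sit not in reachable:
            return _reject
        return resident.distribution(sit)

    lam_by_status = {
        VIRGIN: rates.lambda_arrivals[FemaleClass(SMALL, VIRGIN)],
        MATED: rates.lambda_arrivals[FemaleClass(SMALL, MATED)],
    }
    for i, size in enumerate(SIZES):
        for o in range(N_OPEN):
            M[i, o, o, 0] = 1.0
    SA_all = None
    if n_search > 1e-300:
        SA_all = np.zeros((2, 2, N_OPEN, N_OPEN, 2 * (J.shape[3] - 1) + 1))
        for i, size in enumerate(SIZES):
            for si, status in enumerate((VIRGIN, MATED)):
                SA_all[i, si] = _single_arrival_operator(
                    J,
                    sigma(VIRGIN, status, size, False, p_v),
                    sigma(MATED, status, size, False, p_m),
                    sigma(MATED, status, size, True, p_v),
                    p_v,
                    p_m,
                )
        for i, size in enumerate(SIZES):
            for si, status in enumerate((VIRGIN, MATED)):
                j = FemaleClass(size, status)
                lam = lam_by_status[status]
                pk = arrival_distribution(lam, k_max)
                arrivals[j] = counts[j] * float(np.arange(k_max + 1) @ pk)
                SA = SA_all[i, si]
                # M is needed for every detailed state a (possibly mutant-
                # created) female could be in, not only the populated ones
                start_openings = [0] if status == VIRGIN else [1, 2]
                for o0 in start_openings:
                    # state after a arrivals: dist over (openings, sperm gained)
                    state = np.zeros((N_OPEN, Lm))
                    state[o0, 0] = 1.0
                    M[i, o0] = pk[0] * state
                    for a in range(1, k_max + 1):
                        nxt = np.zeros_like(state)
                        for o in range(N_OPEN):
                            if state[o].any():
                                for o1 in range(N_OPEN):
                                    if SA[o, o1].any():
                                        conv = np.convolve(state[o], SA[o, o1])[:Lm]
                                        nxt[o1, : conv.size] += conv
                        state = nxt
                        M[i, o0] += pk[a] * state

    F_new = np.zeros_like(pop.females)
    for i in range(2):
        for o0 in range(N_OPEN):
            col = pop.females[i, o0]
            if not col.any():
                continue
            for o1 in range(N_OPEN):
                if M[i, o0, o1].any():
                    F_new[i, o1] += _conv_sat(col, M[i, o0, o1], cap)
    sperm_before = float(np.einsum("ioy,y->", pop.females, np.arange(cap + 1)))
    sperm_after = float(np.einsum("ioy,y->", F_new, np.arange(cap + 1)))
    pop.females = F_new

    # -- male pool update from per-arrival action statistics ----------------
    leave_virgin = 0.0
    join_mated = 0.0
    leave_mated = 0.0
    for j, n_arr in arrivals.items():
        if n_arr <= 0.0:
            continue
        sv = sigma(VIRGIN, j.status, j.size, False, p_v)
        sm = sigma(MATED, j.status, j.size, False, p_m)
        sjm = sigma(MATED, j.status, j.size, True, p_v)
        c = np.arange(11)
        accept_v = sv[1:].sum()
        surv_to_jm = float(sv @ np.where(c > 0, 1.0 - c / 10.0, 0.0))
        leave_virgin += n_arr * p_v * accept_v
        join_mated += n_arr * p_v * surv_to_jm * sjm[0]
        leave_mated += n_arr * p_m * sm[1:].sum()
    pop.males_virgin -= leave_virgin
    pop.males_mated += join_mated - leave_mated

    # -- mortality (skipped after the final matings) ------------------------
    if t < params.t_max:
        pop.subadult_females *= 1.0 - params.mortality_female
        pop.subadult_males *= 1.0 - params.mortality_male
        pop.males_virgin *= 1.0 - params.mortality_male
        pop.males_mated *= 1.0 - params.mortality_male
        pop.females *= 1.0 - params.mortality_female

    record = StepRecord(
        t=t,
        rates=rates,
        D=D,
        M=M,
        SA=SA_all,
        lam_by_status=lam_by_status,
        arrivals=arrivals,
        p_virgin_male=p_v,
        p_mated_male=p_m,
        sperm_added=sperm_after - sperm_before,
    )
    return pop.check(), record


def run_season(resident: Strategy, params: ModelParameters) -> Season:
    """Run one full season from the initial subadult population."""
    pop = PopulationState.initial(params)
    trajectory = [pop.copy()]
    records = []
    for t in range(1, params.t_max + 1):
        pop, rec = step_population(pop, resident, params, t)
        trajectory.append(pop)
        records.append(rec)
    return Season(params=params, resident=resident, records=records, trajectory=trajectory)


def competition_kernel(season: Season) -> np.ndarray:
    """Future-competition kernel K[t, size, openings, y].

    For a female in the given detailed state at the end of step t's mating
    phase, ``K[t, size, o]`` is the joint distribution of the additional
    competing sperm y she will receive from later steps and her survival to
    oviposition (total mass = survival probability).  Boundary: at t_max the
    season ends, so the kernel is a unit point mass at y = 0.
    """
    params = season.params
    cap = params.solver.sperm_cap
    t_max = params.t_max
    K = np.zeros((t_max + 1, 2, N_OPEN, cap + 1))
    K[t_max, :, :, 0] = 1.0
    surv = 1.0 - params.mortality_female
    for t in range(t_max - 1, 0, -1):
        M = season.record(t + 1).M
        for i in range(2):
            for o in range(N_OPEN):
                acc = np.zeros(cap + 1)
                for o1 in range(N_OPEN):
                    if M[i, o, o1].any():
                        acc += _conv_sat(M[i, o, o1], K[t + 1, i, o1], cap)
                K[t, i, o] = surv * acc
    return K


def build_environment(resident: Strategy, params: ModelParameters) -> SeasonEnvironment:
    """Forward pass plus kernel: the full environment induced by a resident."""
    season = run_season(resident, params)
    return SeasonEnvironment(
        params=params, resident=resident, season=season, kernel=competition_kernel(season)
    )
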