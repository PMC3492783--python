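"""Backward dynamic programming of male reproductive values against a
frozen resident-generated environment, with error-smoothed decisions.

The reproductive value V[status, t] is the expected number of offspring a
male in the given mating status produces from step t onward.  Working from
the final step backwards, the value of every action in every situation is
computed from the immediate fair-raffle paternity gain plus the
survival-weighted continuation value, and decisions are smoothed with an
exponential (logit-type) error rule so that costlier errors occur less
frequently.  The smoothed strategy is what the ESS loop feeds back as the
next resident.

Because all males at a site move simultaneously and interact in random
order, a focal male evaluating a female must account for rivals within the
same time step: his position among the step's Poisson arrivals is uniform,
rivals acting before him shift the female's hidden opening/sperm state away
from the start-of-step distribution, and rivals acting after him add
competing sperm before the between-step competition kernel takes over.
The backward pass enumerates these (n_before, n_after) scenarios exactly,
using the same one-arrival operator as the forward pass, which keeps
mutant valuation and resident dynamics consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encounter import arrival_distribution
from .forward import _BRANCHES, N_OPEN, SIZES, SeasonEnvironment, StepRecord, _conv_sat
from .mating import sperm_distributions
from .states import (
    MATED,
    N_ACTIONS,
    VIRGIN,
    Openings,
    Situation,
    Strategy,
    enumerate_situations,
)

__all__ = [
    "ValueTable",
    "smooth",
    "expected_gain",
    "action_value",
    "backward_induction",
]

_OPEN_INDEX = {Openings.VIRGIN: 0, Openings.HALF_PLUGGED: 1, Openings.FULLY_PLUGGED: 2}
_STATUS_INDEX = {VIRGIN: 0, MATED: 1}


@dataclass
class ValueTable:
    """Values, action values, argmax actions and smoothed decision rows."""

    #: V[status, t] for status 0 = virgin, 1 = mated; t = 1..t_max (+1 boundary = 0)
    V: np.ndarray
    Q: dict[Situation, np.ndarray]
    best: dict[Situation, int]
    smoothed: Strategy

    def value(self, male_status: str, t: int) -> float:
        return float(self.V[_STATUS_INDEX[male_status], t])


def smooth(q_row: np.ndarray, delta: float, absolute_scale: bool = False) -> np.ndarray:
    """Error-smoothed action distribution from a row of action values.

    Weights are ``exp(-(V* - Q(c)) / (delta * scale))`` with V* the best
    value in the row and ``scale = max(V*, 1e-12)`` (relative shortfall;
    ``absolute_scale`` switches to scale = 1).  delta -> 0 recovers the pure
    argmax; equal values give the uniform distribution.
    """
    q = np.asarray(q_row, dtype=float)
    finite = np.isfinite(q)
    if not finite.any():
        raise ValueError("smooth() needs at least one finite action value")
    vstar = q[finite].max()
    scale = 1.0 if absolute_scale else max(vstar, 1e-12)
    w = np.zeros_like(q)
    arg = -(vstar - q[finite]) / (delta * scale)
    w[finite] = np.exp(np.maximum(arg, -745.0))
    return w / w.sum()


def _class_state(D: np.ndarray, size_idx: int, status: str, cap: int) -> np.ndarray:
    """Joint (openings, stored sperm) distribution of one observable class
    at the start of the step, with a nominal fallback when the class mass
    is zero (virgin -> pristine; mated -> half-plugged, empty)."""
    J0 = np.zeros((N_OPEN, cap + 1))
    if status == VIRGIN:
        mass = D[size_idx, 0].sum()
        if mass < 1e-300:
            J0[0, 0] = 1.0
        else:
            J0[0] = D[size_idx, 0] / mass
        return J0
    mass = D[size_idx, 1:].sum()
    if mass < 1e-300:
        J0[1, 0] = 1.0
    else:
        J0[1:] = D[size_idx, 1:] / mass
    return J0


@dataclass
class _Scenario:
    """One (n_before, n_after) rival configuration for the focal arrival."""

    weight: float
    #: P(hidden opening detail at the focal male's turn)
    wd: np.ndarray  # [3]
    #: G[d, o_post, x]: expected offspring from x own units given detail d
    #: at the turn and post-copulation opening state o_post
    G: np.ndarray  # [3, 3, x_max + 1]
    #: T[d, u2, x1, c2-1]: value of attempting a second copulation for c2
    #: seconds into a (used? u2) opening with x1 own units already placed
    T: np.ndarray  # [3, 2, 11, 10]


def _build_scenarios(
    env: SeasonEnvironment,
    rec: StepRecord,
    t: int,
    size_idx: int,
    status: str,
    Jsum: np.ndarray,
    x_max: int,
) -> list[_Scenario]:
    params = env.params
    cap = params.solver.sperm_cap
    k_max = params.solver.arrival_k_max
    fec = params.fecundity_small if size_idx == 0 else 1.0
    n_s = Jsum.shape[2]
    K_future = env.kernel[t, size_idx]  # [3, cap+1]

    J0 = _class_state(rec.D, size_idx, status, cap)
    if rec.SA is None:
        pairs = {(0, 0): 1.0}
        SA = None
    else:
        SA = rec.SA[size_idx, 0 if status == VIRGIN else 1]
        pk = arrival_distribution(rec.lam_by_status[status], k_max)
        pairs = {}
        for k in range(k_max + 1):
            for n_before in range(k + 1):
                pairs[(n_before, k - n_before)] = (
                    pairs.get((n_before, k - n_before), 0.0) + pk[k] / (k + 1)
                )

    max_b = max(b for b, _ in pairs)
    max_a = max(a for _, a in pairs)
    # hidden state after n_before rivals
    A = [J0]
    for _ in range(max_b):
        prev = A[-1]
        nxt = np.zeros_like(prev)
        for o in range(N_OPEN):
            if prev[o].any():
                for o1 in range(N_OPEN):
                    if SA[o, o1].any():
                        nxt[o1] += _conv_sat(prev[o], SA[o, o1], cap)
        A.append(nxt)
    # effective kernel after n_after rivals act on the post-focal state
    P = [np.zeros((N_OPEN, N_OPEN, 1))]
    P[0][np.arange(N_OPEN), np.arange(N_OPEN), 0] = 1.0
    for _ in range(max_a):
        prev = P[-1]
        nxt = np.zeros((N_OPEN, N_OPEN, min(prev.shape[2] + SA.shape[2] - 1, cap + 1)))
        for o in range(N_OPEN):
            for m in range(N_OPEN):
                if prev[o, m].any():
                    for o1 in range(N_OPEN):
                        if SA[m, o1].any():
                            nxt[o, o1] += _conv_sat(prev[o, m], SA[m, o1], cap)[: nxt.shape[2]]
        P.append(nxt)
    K_eff = []
    for a in range(max_a + 1):
        Ka = np.zeros((N_OPEN, cap + 1))
        for o_p in range(N_OPEN):
            for o_e in range(N_OPEN):
                if P[a][o_p, o_e].any():
                    Ka[o_p] += _conv_sat(P[a][o_p, o_e], K_future[o_e], cap)
        K_eff.append(Ka)

    xs = np.arange(x_max + 1, dtype=float)
    scenarios = []
    for (b, a), q in sorted(pairs.items()):
        wd = A[b].sum(axis=1)
        G = np.zeros((N_OPEN, N_OPEN, x_max + 1))
        for d in range(N_OPEN):
            if wd[d] <= 1e-300:
                continue
            y0 = A[b][d] / wd[d]
            for o_p in range(N_OPEN):
                Z = np.convolve(y0, K_eff[a][o_p])
                ws = np.arange(Z.size, dtype=float)
                shares = np.zeros((x_max + 1, Z.size))
                nz = xs > 0
                shares[nz] = xs[nz, None] / (xs[nz, None] + ws[None, :])
                G[d, o_p] = fec * (shares @ Z)
        # sliding windows of G[., fully_plugged] give second-copulation values
        T = np.zeros((N_OPEN, 2, 11, 10))
        for d in range(N_OPEN):
            W = np.stack([G[d, 2, x1 : x1 + n_s] for x1 in range(11)])
            for u2 in (0, 1):
                T[d, u2] = W @ Jsum[u2, 1:, :].T
        scenarios.append(_Scenario(weight=q, wd=wd, G=G, T=T))
    return scenarios


def expected_gain(
    x: float,
    size: str,
    openings_before: Openings,
    openings_after: Openings,
    t: int,
    env: SeasonEnvironment,
) -> float:
    """Expected offspring from ``x`` units of own sperm placed in a female.

    ``openings_before`` conditions the hidden stored-sperm distribution on
    the start-of-step state; ``openings_after`` selects the competition-
    kernel state she is left in.  Fair raffle: the male's share is
    x / (x + prior + future competing sperm), weighted by her survival to
    oviposition and her size-dependent fecundity.  This is the between-step
    quantity (same-step rivals are handled scenario-wise inside
    :func:`backward_induction`).
    """
    if x < 0:
        raise ValueError("x must be >= 0")
    if x == 0:
        return 0.0
    params = env.params
    i = SIZES.index(size)
    D = env.record(t).D
    col = D[i, _OPEN_INDEX[openings_before]]
    y0 = col / col.sum() if col.sum() > 1e-300 else None
    K = env.kernel[t, i, _OPEN_INDEX[openings_after]]
    Z = K if y0 is None else np.convolve(y0, K)
    ws = np.arange(Z.size, dtype=float)
    fec = params.fecundity_small if size == SIZES[0] else 1.0
    return float(fec * np.sum(Z * (x / (x + ws))))


_FALLBACK_FIRST = np.zeros(N_ACTIONS)
_FALLBACK_FIRST[1:10] = 1.0 / 9.0  # survivable first copulations, uniform


def _resident_row(env: SeasonEnvironment, sit: Situation) -> np.ndarray:
    try:
        return env.resident.distribution(sit)
    except KeyError:
        return _FALLBACK_FIRST


def backward_induction(env: SeasonEnvironment) -> ValueTable:
    """Fill Q, argmax and smoothed rows for t = t_max..1 and the V recursion.

    V[status, t] = sum_j find_j * W[status, j, t]
                 + (1 - sum_j find_j) * (1 - mortality_male) * V[status, t+1],
    with W the smoothed-average action value upon meeting class j and
    V[., t_max + 1] = 0.
    """
    params = env.params
    t_max = params.t_max
    m_surv = 1.0 - params.mortality_male
    delta = params.error_delta
    absolute = params.error_absolute_scale
    plug = params.plug
    J = sperm_distributions(params)
    n_s = J.shape[3]
    Jsum = J[:, 0] + J[:, 1]  # [used, c, s]: sperm dist irrespective of male fate
    x_max = 10 + (n_s - 1)
    c_arr = np.arange(N_ACTIONS)
    surv_c = 1.0 - c_arr / 10.0

    V = np.zeros((2, t_max + 2))
    all_Q: dict[Situation, np.ndarray] = {}
    all_smoothed: dict[Situation, np.ndarray] = {}
    reachable = set(enumerate_situations(t_max))

    for t in range(t_max, 0, -1):
        rec = env.record(t)
        for fstat in (VIRGIN, MATED):
            for i, size in enumerate(SIZES):
                scen = _build_scenarios(env, rec, t, i, fstat, Jsum, x_max)

                # ---- just-mated row (second copulation with the same female)
                sit_jm = Situation(MATED, fstat, size, True, t)
                sigma_first = _resident_row(env, Situation(VIRGIN, fstat, size, False, t))
                norm = float(sigma_first[1:] @ surv_c[1:])
                if norm <= 1e-15:
                    sigma_first = _FALLBACK_FIRST
                    norm = float(sigma_first[1:] @ surv_c[1:])
                # weight over own first-copulation transfer x1, given survival
                wx1_raw = np.zeros(11)
                wx1_raw[1:] = sigma_first[1:] * surv_c[1:] / norm
                q_jm = np.zeros(N_ACTIONS)
                q_jm[0] = m_surv * V[1, t + 1]
                for sc in scen:
                    for d in range(N_OPEN):
                        if sc.wd[d] <= 0.0:
                            continue
                        for hb, u1, o1, u2 in _BRANCHES[d]:
                            w = sc.weight * sc.wd[d] * hb
                            if u1 == 0:
                                wx1 = wx1_raw
                            else:  # plug may have voided his first transfer
                                wx1 = (1 - plug) * wx1_raw
                                wx1 = wx1.copy()
                                wx1[0] += plug
                            q_jm[0] += w * float(wx1 @ sc.G[d, o1, :11])
                            q_jm[1:] += w * (wx1 @ sc.T[d, u2])
                all_Q[sit_jm] = q_jm
                sigma_jm = smooth(q_jm, delta, absolute)
                all_smoothed[sit_jm] = sigma_jm

                # ---- mated male meeting an unrelated female
                sit_m = Situation(MATED, fstat, size, False, t)
                q_m = np.zeros(N_ACTIONS)
                q_m[0] = m_surv * V[1, t + 1]
                for sc in scen:
                    for d in range(N_OPEN):
                        if sc.wd[d] <= 0.0:
                            continue
                        for hb, u1, o1, _u2 in _BRANCHES[d]:
                            q_m[1:] += (
                                sc.weight * sc.wd[d] * hb * (Jsum[u1, 1:, :] @ sc.G[d, o1, :n_s])
                            )
                all_Q[sit_m] = q_m
                all_smoothed[sit_m] = smooth(q_m, delta, absolute)

                # ---- virgin male meeting a female (first copulation)
                sit_v = Situation(VIRGIN, fstat, size, False, t)
                q_v = np.zeros(N_ACTIONS)
                q_v[0] = m_surv * V[0, t + 1]
                leave_value = m_surv * V[1, t + 1]
                for sc in scen:
                    for d in range(N_OPEN):
                        if sc.wd[d] <= 0.0:
                            continue
                        for hb, u1, o1, u2 in _BRANCHES[d]:
                            w = sc.weight * sc.wd[d] * hb
                            # killed during the first copulation: his sperm
                            # stays (with the post-attack extension), no future
                            q_v[1:] += w * (J[u1, 0, 1:, :] @ sc.G[d, o1, :n_s])
                            # survived: just-mated continuation with x1 own
                            # units already in her (smoothed second decision)
                            cv = (
                                sigma_jm[0] * (sc.G[d, o1, :11] + leave_value)
                                + sc.T[d, u2] @ sigma_jm[1:]
                            )
                            if u1 == 0:
                                q_v[1:] += w * surv_c[1:] * cv[1:]
                            else:
                                q_v[1:] += w * surv_c[1:] * (plug * cv[0] + (1 - plug) * cv[1:])
                all_Q[sit_v] = q_v
                all_smoothed[sit_v] = smooth(q_v, delta, absolute)

        # ---- V recursion for this t
        find = rec.rates.find
        p_any = rec.rates.p_find_any
        for ms, msi in ((VIRGIN, 0), (MATED, 1)):
            v = (1.0 - p_any) * m_surv * V[msi, t + 1]
            for j, fj in find.items():
                if fj <= 0.0:
                    continue
                sit = Situation(ms, j.status, j.size, False, t)
                v += fj * float(all_smoothed[sit] @ all_Q[sit])
            V[msi, t] = v

    Q = {s: q for s, q in all_Q.items() if s in reachable}
    best = {s: int(np.argmax(q)) for s, q in Q.items()}
    smoothed = Strategy({s: r for s, r in all_smoothed.items() if s in reachable})
    return ValueTable(V=V, Q=Q, best=best, smoothed=smoothed)


def action_value(sit: Situation, c: int, values: ValueTable) -> float:
    """Expected offspring from taking action c in the given situation."""
    return float(values.Q[sit][c])
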