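"""Evolutionarily stable strategy by damped smoothed-best-response
iteration: alternate forward (season under the resident) and backward
(mutant dynamic programming) passes until the smoothed best response
reproduces the resident, then summarize equilibrium behavior.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from . import __version__
from .backward import ValueTable, backward_induction
from .config import ModelParameters, save_config, validate
from .forward import SeasonEnvironment, build_environment
from .states import MATED, VIRGIN, Situation, Strategy, enumerate_situations

logger = logging.getLogger(__name__)

__all__ = [
    "EquilibriumResult",
    "OutcomeTriple",
    "NoMatingError",
    "solve",
    "outcome_probabilities",
    "acceptance_probability",
    "acceptance_table",
    "outcome_table",
    "season_aggregated_outcomes",
    "result_to_dir",
]


class NoMatingError(ValueError):
    """Raised when a conditional outcome is requested for a situation whose
    smoothed mating probability is (numerically) zero."""


class OutcomeTriple(NamedTuple):
    """Conditional fates of a virgin male who decides to mate:
    killed during the first copulation (monogyny type 1), second copulation
    with the same female (monogyny type 2), or leaving after one (bigyny)."""

    monogyny1: float
    monogyny2: float
    bigyny: float


@dataclass
class EquilibriumResult:
    resident: Strategy
    values: ValueTable
    env: SeasonEnvironment
    iterations: int
    converged: bool
    residual: float

    @property
    def params(self) -> ModelParameters:
        return self.env.params


def solve(
    params: ModelParameters,
    initial: Optional[Strategy] = None,
    progress: bool = False,
) -> EquilibriumResult:
    """Iterate forward and backward passes to a smoothed best-response
    fixed point.

    Starting from a uniform resident (or ``initial``), each cycle derives
    the environment the resident induces, computes the error-smoothed best
    response, and blends it into the resident with the damping weight.  The
    residual is the sup-norm gap between the resident and its best
    response; convergence means residual < ``convergence_tol``.  The whole
    procedure is deterministic.  Non-convergence is reported via
    ``converged=False``, never silently.
    """
    validate(params)
    tol = params.solver.convergence_tol
    damping = params.solver.damping
    resident = initial if initial is not None else Strategy.uniform(params.t_max)
    residual = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, params.solver.max_iterations + 1):
        env = build_environment(resident, params)
        vt = backward_induction(env)
        response = vt.smoothed
        residual = resident.sup_distance(response)
        if progress:
            logger.info("iteration %d: residual %.3e", iterations, residual)
        resident = resident.mix(response, damping)
        if residual < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "no convergence after %d iterations (residual %.3e > tol %.1e)",
            iterations, residual, tol,
        )
    # final consistent environment and values for the returned resident
    env = build_environment(resident, params)
    vt = backward_induction(env)
    return EquilibriumResult(
        resident=resident,
        values=vt,
        env=env,
        iterations=iterations,
        converged=converged,
        residual=float(residual),
    )


def outcome_probabilities(eq: EquilibriumResult, sit: Situation) -> OutcomeTriple:
    """Conditional mating-outcome triple for a virgin-male situation.

    Conditional on deciding to mate (c1 > 0) under the smoothed resident:
    monogyny 1 = death during the first copulation (probability c1/10);
    monogyny 2 = surviving and then copulating again with the same female;
    bigyny = surviving and leaving her.  The three sum to one.
    """
    if sit.male_status != VIRGIN or sit.just_mated:
        raise ValueError("outcome probabilities are defined for virgin-male first encounters")
    sigma = eq.resident.distribution(sit)
    p_mate = float(sigma[1:].sum())
    if p_mate < 1e-12:
        raise NoMatingError(f"no mating occurs in {sit}")
    sit_jm = Situation(MATED, sit.female_status, sit.female_size, True, sit.t)
    p_second = 1.0 - float(eq.resident.distribution(sit_jm)[0])
    c = np.arange(11)
    w = sigma / p_mate
    p1 = float(np.sum(w[1:] * c[1:] / 10.0))
    surv = float(np.sum(w[1:] * (1.0 - c[1:] / 10.0)))
    return OutcomeTriple(monogyny1=p1, monogyny2=surv * p_second, bigyny=surv * (1.0 - p_second))


def acceptance_probability(eq: EquilibriumResult, sit: Situation) -> float:
    """Probability that a male decides to mate (does not reject) in ``sit``."""
    return 1.0 - float(eq.resident.distribution(sit)[0])


def _first_encounter_situations(eq: EquilibriumResult):
    for sit in enumerate_situations(eq.params.t_max):
        if not sit.just_mated:
            yield sit


def _mating_weight(eq: EquilibriumResult, sit: Situation) -> float:
    """Expected number of resident decisions of this situation's kind in the
    forward pass (arrivals of males of that status at that female class)."""
    rec = eq.env.record(sit.t)
    share = rec.p_virgin_male if sit.male_status == VIRGIN else rec.p_mated_male
    for j, n in rec.arrivals.items():
        if j.size == sit.female_size and j.status == sit.female_status:
            return n * share
    return 0.0


def acceptance_table(eq: EquilibriumResult) -> pd.DataFrame:
    """Per-situation acceptance probabilities with forward-pass weights."""
    recs = []
    for sit in _first_encounter_situations(eq):
        recs.append(
            dict(
                male_status=sit.male_status,
                female_status=sit.female_status,
                female_size=sit.female_size,
                t=sit.t,
                acceptance=acceptance_probability(eq, sit),
                weight=_mating_weight(eq, sit),
            )
        )
    return pd.DataFrame.from_records(recs)


def outcome_table(eq: EquilibriumResult) -> pd.DataFrame:
    """Per-situation conditional outcome triples for virgin males."""
    recs = []
    for sit in _first_encounter_situations(eq):
        if sit.male_status != VIRGIN:
            continue
        triple = outcome_probabilities(eq, sit)
        weight = _mating_weight(eq, sit) * acceptance_probability(eq, sit)
        recs.append(
            dict(
                female_status=sit.female_status,
                female_size=sit.female_size,
                t=sit.t,
                monogyny1=triple.monogyny1,
                monogyny2=triple.monogyny2,
                bigyny=triple.bigyny,
                weight=weight,
            )
        )
    return pd.DataFrame.from_records(recs)


def season_aggregated_outcomes(eq: EquilibriumResult) -> pd.DataFrame:
    """Outcome triples aggregated over the season, weighted by the expected
    number of matings of each kind in the resident forward pass; includes
    one row per female class and an overall row (female_status = 'any')."""
    tbl = outcome_table(eq)
    rows = []
    groups = list(tbl.groupby(["female_status", "female_size"], sort=True))
    groups.append((("any", "any"), tbl))
    for (fstat, fsize), grp in groups:
        w = grp["weight"].to_numpy()
        total = w.sum()
        if total <= 0:
            rows.append(dict(female_status=fstat, female_size=fsize, weight=0.0,
                             monogyny1=np.nan, monogyny2=np.nan, bigyny=np.nan))
            continue
        rows.append(
            dict(
                female_status=fstat,
                female_size=fsize,
                weight=total,
                **{k: float(np.average(grp[k], weights=w)) for k in
                   ("monogyny1", "monogyny2", "bigyny")},
            )
        )
    return pd.DataFrame.from_records(rows)


def values_table(eq: EquilibriumResult) -> pd.DataFrame:
    recs = [
        dict(male_status=ms, t=t, value=eq.values.value(ms, t))
        for ms in (VIRGIN, MATED)
        for t in range(1, eq.params.t_max + 1)
    ]
    return pd.DataFrame.from_records(recs)


def result_to_dir(eq: EquilibriumResult, out_dir: str | Path) -> Path:
    """Serialize an equilibrium to a directory of flat text tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(eq.params, out / "parameters.yaml")
    eq.resident.to_frame().to_csv(out / "strategy.csv", index=False)
    values_table(eq).to_csv(out / "values.csv", index=False)
    acceptance_table(eq).to_csv(out / "acceptance.csv", index=False)
    outcome_table(eq).to_csv(out / "outcomes.csv", index=False)
    season_aggregated_outcomes(eq).to_csv(out / "outcomes_aggregated.csv", index=False)
    meta = dict(
        iterations=eq.iterations,
        converged=bool(eq.converged),
        residual=eq.residual,
        damping=eq.params.solver.damping,
        version=__version__,
    )
    (out / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return out
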