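"""Single-copulation mechanics: cannibalism risk, the post-attack extension,
sperm transfer and mating-plug failure, and resolution of which genital
opening a copulation hits.

A male attempting to copulate for c seconds (c in 0..10) is attacked at a
time T uniform on the ticks {1, ..., 10}; if T > c he escapes after c
seconds having transferred c units of sperm (one unit per second), otherwise
he is killed and — because he never attempted to escape before the attack —
keeps transferring for ``delta_extension`` seconds beyond T.  This
discretization realizes the linear survival law P(survive | c) = 1 - c/10
exactly while keeping sperm integer-valued.  A copulation into a previously
used opening transfers nothing with probability ``plug`` (all-or-nothing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import ModelParameters
from .states import FemaleState, Openings

__all__ = [
    "CopulationOutcome",
    "OutcomeDistribution",
    "survival_probability",
    "outcome_distribution",
    "expected_sperm",
    "opening_used_probability",
    "sperm_distributions",
]

#: number of attack ticks within the risky window
_TICKS = 10


@dataclass(frozen=True)
class CopulationOutcome:
    survived: bool
    sperm_transferred: int
    opening_was_used: bool


class OutcomeDistribution:
    """Finite distribution over copulation outcomes (probabilities sum to 1)."""

    def __init__(self, items: list[tuple[CopulationOutcome, float]]):
        total = sum(p for _, p in items)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"outcome probabilities sum to {total}, not 1")
        # merge duplicates for a canonical support
        merged: dict[CopulationOutcome, float] = {}
        for out, p in items:
            if p < 0:
                raise ValueError("negative outcome probability")
            if p > 0:
                merged[out] = merged.get(out, 0.0) + p
        self.items: list[tuple[CopulationOutcome, float]] = sorted(
            merged.items(), key=lambda op: (op[0].survived, op[0].sperm_transferred)
        )

    def probability(self, **conditions) -> float:
        """Total probability of outcomes matching all keyword conditions."""
        return sum(
            p for out, p in self.items
            if all(getattr(out, k) == v for k, v in conditions.items())
        )

    def expected_sperm(self) -> float:
        return sum(p * out.sperm_transferred for out, p in self.items)

    def survival(self) -> float:
        return self.probability(survived=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(
            [
                dict(survived=o.survived, sperm=o.sperm_transferred,
                     opening_was_used=o.opening_was_used, probability=p)
                for o, p in self.items
            ]
        )


def _check_c(c: int) -> int:
    if int(c) != c or not (0 <= c <= _TICKS):
        raise ValueError(f"attempted duration c={c!r} must be an integer in [0, {_TICKS}]")
    return int(c)


def survival_probability(c: int) -> float:
    """P(the male survives a copulation attempted for c seconds) = 1 - c/10."""
    c = _check_c(c)
    return 1.0 - c / _TICKS


def _raw_outcomes(c: int, params: ModelParameters) -> list[tuple[bool, int, float]]:
    """(survived, raw sperm, probability) triples before plug resolution."""
    if c == 0:
        return [(True, 0, 1.0)]
    delta = int(params.delta_extension)
    out = []
    if c < _TICKS:
        out.append((True, c, 1.0 - c / _TICKS))
    for attack_t in range(1, c + 1):
        gains_delta = params.delta_on_interrupted or c == _TICKS
        sperm = attack_t + (delta if gains_delta else 0)
        out.append((False, sperm, 1.0 / _TICKS))
    return out


def outcome_distribution(
    c: int, opening_used: bool, params: ModelParameters
) -> OutcomeDistribution:
    """Exact distribution of (survival, transferred sperm) for one copulation.

    ``opening_used`` flags whether the opening the male copulates into has
    been used before; if so, with probability ``plug`` the whole transfer
    fails (sperm replaced by 0).  c = 0 yields the single outcome
    (survived, 0 units).
    """
    c = _check_c(c)
    items: list[tuple[CopulationOutcome, float]] = []
    for survived, sperm, p in _raw_outcomes(c, params):
        if opening_used and c > 0:
            if params.plug > 0:
                items.append((CopulationOutcome(survived, 0, True), p * params.plug))
            if params.plug < 1:
                items.append((CopulationOutcome(survived, sperm, True), p * (1 - params.plug)))
        else:
            items.append((CopulationOutcome(survived, sperm, opening_used), p))
    return OutcomeDistribution(items)


def expected_sperm(c: int, opening_used: bool, params: ModelParameters) -> float:
    """Expected units of sperm transferred by one copulation."""
    return outcome_distribution(c, opening_used, params).expected_sperm()


def opening_used_probability(
    context: str,
    female: FemaleState | Openings,
    first_copulation_hit_used: Optional[bool] = None,
) -> float:
    """Probability that the copulation hits a previously used opening.

    ``context`` is one of ``virgin_male_first``, ``mated_male_unrelated``
    (any first copulation between an unrelated pair) or
    ``same_female_second`` (a male's immediate second copulation with the
    female he just mated).  Because insemination is ipsilateral (left palp
    -> left opening), an unrelated male hits either side with probability
    1/2 on a half-plugged female, while a same-pair second copulation is
    forced onto the complementary side of the first.
    """
    openings = female.openings if isinstance(female, FemaleState) else female
    if context in ("virgin_male_first", "mated_male_unrelated"):
        return {Openings.VIRGIN: 0.0, Openings.HALF_PLUGGED: 0.5, Openings.FULLY_PLUGGED: 1.0}[
            openings
        ]
    if context == "same_female_second":
        # `openings` is the female's state on the pair's FIRST encounter.
        if openings is Openings.VIRGIN:
            return 0.0  # his first hit one unused side; the other is unused too
        if openings is Openings.FULLY_PLUGGED:
            return 1.0
        if first_copulation_hit_used is None:
            raise ValueError(
                "same_female_second on a half-plugged female requires first_copulation_hit_used"
            )
        return 0.0 if first_copulation_hit_used else 1.0
    raise ValueError(f"unknown context {context!r}")


def sperm_distributions(params: ModelParameters) -> np.ndarray:
    """Per-(used flag, c) joint arrays of sperm transfer and male survival.

    Returns an array ``J[used, surv, c, s]`` with ``J[u, 1, c, s]`` the
    probability that the male survives and transfers s units, and
    ``J[u, 0, c, s]`` the same for being killed; s runs over
    0..(10 + delta_extension).  Used by the mean-field season machinery.
    """
    n_s = _TICKS + int(params.delta_extension) + 1
    J = np.zeros((2, 2, _TICKS + 1, n_s))
    for used in (0, 1):
        for c in range(_TICKS + 1):
            for out, p in outcome_distribution(c, bool(used), params).items:
                J[used, int(out.survived), c, out.sperm_transferred] += p
    return J
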