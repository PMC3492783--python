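"""Pheromone-weighted mate search.

Each step every searching male moves to a random site.  A site occupied by
an adult female is `a` times as likely to be visited as an empty one, with
`a` = ``attract_virgin`` or ``attract_mated`` depending on her status.  With
W the total site weight, a male finds a class-j female with probability
f_j * a_j / W, and a given class-j female receives on average
n_searching * a_j / W male arrivals.  Arrival numbers at one female's site
are modelled as Poisson, truncated at ``arrival_k_max`` with the tail mass
folded into the top bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import ModelParameters
from .states import FemaleClass, MATED, VIRGIN

__all__ = ["EncounterRates", "encounter_rates", "arrival_distribution"]


@dataclass(frozen=True)
class EncounterRates:
    """Per-class find probabilities and per-female arrival intensities."""

    find: dict[FemaleClass, float]
    p_empty: float
    lambda_arrivals: dict[FemaleClass, float]

    @property
    def p_find_any(self) -> float:
        return sum(self.find.values())


def _attract(params: ModelParameters, status: str) -> float:
    return params.attract_virgin if status == VIRGIN else params.attract_mated


def encounter_rates(
    female_counts: dict[FemaleClass, float],
    n_searching_males: float,
    params: ModelParameters,
) -> EncounterRates:
    """Find probabilities and arrival intensities for the current step.

    ``female_counts`` are adult-female masses per observable class, in units
    of the initial subadult-female count; they may not exceed the number of
    sites ``sites_per_female``.
    """
    S = params.sites_per_female
    total_f = sum(female_counts.values())
    if any(v < 0 for v in female_counts.values()) or n_searching_males < 0:
        raise ValueError("negative mass")
    if total_f > S * (1 + 1e-12):
        raise ValueError(f"more females than sites ({total_f} > {S})")
    n_empty = max(S - total_f, 0.0)
    W = n_empty + sum(_attract(params, j.status) * f for j, f in female_counts.items())
    find = {j: f * _attract(params, j.status) / W for j, f in female_counts.items()}
    lam = {j: n_searching_males * _attract(params, j.status) / W for j in female_counts}
    return EncounterRates(find=find, p_empty=n_empty / W, lambda_arrivals=lam)


def arrival_distribution(lam: float, k_max: int = 3) -> np.ndarray:
    """P(k males arrive at a given female's site), k = 0..k_max.

    Poisson(lam) with the tail mass P(K > k_max) folded into the k_max bin.
    """
    if lam < 0:
        raise ValueError("negative arrival intensity")
    k = np.arange(k_max + 1)
    p = stats.poisson.pmf(k, lam)
    p[-1] += stats.poisson.sf(k_max, lam)
    return p
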