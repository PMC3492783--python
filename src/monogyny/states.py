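"""Male and female state types, the male-observable female class, decision
situations, and (possibly stochastic) strategies.

Males can be subadult, virgin adults, or mated adults; a "mated" male has
used exactly one of his two pedipalps (both-used males can no longer mate
and are dropped from all bookkeeping).  A female is described by her size,
the used/unused flags of her two genital openings, and her stored sperm —
but a male perceives only her size and whether she is a virgin.

A decision situation is the tuple (male status, female status on the male's
arrival, female size, whether the focal pair has just mated in this step,
time step).  Only biologically reachable combinations exist: a just-mated
male is necessarily mated, and in the very first step no adult female can
already be mated when males arrive.  The number of reachable situations is
12*t_max - 8.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "SMALL",
    "LARGE",
    "VIRGIN",
    "MATED",
    "MaleStatus",
    "Openings",
    "FemaleState",
    "FemaleClass",
    "Situation",
    "Strategy",
    "N_ACTIONS",
    "enumerate_situations",
    "perceive",
]

SMALL = "small"
LARGE = "large"
VIRGIN = "virgin"
MATED = "mated"

#: attempted copulation durations c in {0, 1, ..., 10}
N_ACTIONS = 11


class MaleStatus(str, Enum):
    SUBADULT = "subadult"
    VIRGIN_ADULT = "virgin"
    MATED_ADULT = "mated"


class Openings(str, Enum):
    """Summary of a female's paired genital openings."""

    VIRGIN = "virgin"          # both unused
    HALF_PLUGGED = "half"      # exactly one used
    FULLY_PLUGGED = "full"     # both used

    @property
    def n_used(self) -> int:
        return {"virgin": 0, "half": 1, "full": 2}[self.value]


@dataclass(frozen=True)
class FemaleState:
    """Full female state: size, per-opening usage, and stored sperm."""

    size: str
    left_used: bool
    right_used: bool
    sperm_total: int = 0

    def __post_init__(self):
        if self.size not in (SMALL, LARGE):
            raise ValueError(f"size must be {SMALL!r} or {LARGE!r}")
        if self.sperm_total < 0:
            raise ValueError("sperm_total must be >= 0")
        if self.openings is Openings.VIRGIN and self.sperm_total != 0:
            raise ValueError("a virgin female cannot store sperm")

    @property
    def openings(self) -> Openings:
        n = int(self.left_used) + int(self.right_used)
        return (Openings.VIRGIN, Openings.HALF_PLUGGED, Openings.FULLY_PLUGGED)[n]


class FemaleClass(NamedTuple):
    """What a male can perceive about a female: size and virginity."""

    size: str
    status: str  # VIRGIN or MATED


def perceive(female: FemaleState) -> FemaleClass:
    """Project a full female state onto what a male can detect.

    Size is carried over unchanged; status is ``virgin`` iff both openings
    are unused.  Which opening was used and how much sperm she stores are
    discarded (a fully plugged female with zero transferred sperm is still
    perceived as mated).
    """
    status = VIRGIN if female.openings is Openings.VIRGIN else MATED
    return FemaleClass(size=female.size, status=status)


class Situation(NamedTuple):
    """One decision context of a male's strategy."""

    male_status: str            # VIRGIN or MATED
    female_status: str          # female's status on the male's arrival
    female_size: str
    just_mated: bool            # True: deciding on a second copulation with the same female
    t: int


def _reachable(sit: Situation, t_max: int) -> bool:
    if sit.t < 1 or sit.t > t_max:
        return False
    if sit.just_mated and sit.male_status != MATED:
        return False  # he has just used a pedipalp
    if sit.t == 1:
        # Adult females first appear in step 1's maturation and all males
        # arrive simultaneously, so every arrival sees a virgin female; no
        # male can already be mated when step 1 begins.  The just-mated
        # follow-up within step 1 is reachable.
        if sit.female_status != VIRGIN:
            return False
        if not sit.just_mated and sit.male_status != VIRGIN:
            return False
    return True


def enumerate_situations(t_max: int) -> list[Situation]:
    """All biologically reachable situations, in deterministic order.

    Order: by t ascending, then non-just-mated before just-mated, then male
    status (virgin, mated), female arrival status (virgin, mated), female
    size (small, large).  The count is 12*t_max - 8.
    """
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    out: list[Situation] = []
    for t in range(1, t_max + 1):
        for jm in (False, True):
            for ms in (VIRGIN, MATED):
                for fs in (VIRGIN, MATED):
                    for size in (SMALL, LARGE):
                        sit = Situation(ms, fs, size, jm, t)
                        if _reachable(sit, t_max):
                            out.append(sit)
    return out


class Strategy:
    """Map from situation to a probability distribution over attempted
    copulation durations c in {0, ..., 10}.

    c = 0 means the male does not attempt to copulate (rejects the female,
    or leaves a just-mated partner to search elsewhere).
    """

    def __init__(self, rows: dict[Situation, np.ndarray]):
        self._rows: dict[Situation, np.ndarray] = {}
        for sit, row in rows.items():
            arr = np.asarray(row, dtype=float)
            if arr.shape != (N_ACTIONS,):
                raise ValueError(f"row for {sit} has shape {arr.shape}, expected ({N_ACTIONS},)")
            if np.any(arr < -1e-12) or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"row for {sit} is not a probability distribution")
            self._rows[sit] = np.clip(arr, 0.0, None) / arr.sum()

    @classmethod
    def uniform(cls, t_max: int) -> "Strategy":
        row = np.full(N_ACTIONS, 1.0 / N_ACTIONS)
        return cls({sit: row.copy() for sit in enumerate_situations(t_max)})

    @classmethod
    def pure_constant(cls, t_max: int, c: int) -> "Strategy":
        row = np.zeros(N_ACTIONS)
        row[c] = 1.0
        return cls({sit: row.copy() for sit in enumerate_situations(t_max)})

    @property
    def situations(self) -> list[Situation]:
        return list(self._rows)

    def distribution(self, sit: Situation) -> np.ndarray:
        return self._rows[sit]

    def argmax_action(self, sit: Situation) -> int:
        """Most probable action (lowest c wins ties)."""
        return int(np.argmax(self._rows[sit]))

    def pure(self) -> "Strategy":
        """The pure strategy concentrating each row on its argmax."""
        rows = {}
        for sit, row in self._rows.items():
            pure = np.zeros(N_ACTIONS)
            pure[int(np.argmax(row))] = 1.0
            rows[sit] = pure
        return Strategy(rows)

    def mix(self, other: "Strategy", weight_self: float) -> "Strategy":
        """Convex combination ``weight_self * self + (1 - weight_self) * other``."""
        if set(self._rows) != set(other._rows):
            raise ValueError("strategies are defined on different situation sets")
        return Strategy(
            {s: weight_self * r + (1.0 - weight_self) * other._rows[s] for s, r in self._rows.items()}
        )

    def sup_distance(self, other: "Strategy") -> float:
        """Sup-norm over all situation/action probabilities."""
        if set(self._rows) != set(other._rows):
            raise ValueError("strategies are defined on different situation sets")
        return max(
            float(np.max(np.abs(r - other._rows[s]))) for s, r in self._rows.items()
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per (situation, action) with its probability."""
        recs = []
        for sit, row in self._rows.items():
            for c, p in enumerate(row):
                recs.append(
                    dict(
                        male_status=sit.male_status,
                        female_status=sit.female_status,
                        female_size=sit.female_size,
                        just_mated=sit.just_mated,
                        t=sit.t,
                        c=c,
                        probability=p,
                    )
                )
        return pd.DataFrame.from_records(recs)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Strategy":
        rows: dict[Situation, np.ndarray] = {}
        for key, grp in frame.groupby(
            ["male_status", "female_status", "female_size", "just_mated", "t"], sort=False
        ):
            sit = Situation(key[0], key[1], key[2], bool(key[3]), int(key[4]))
            row = np.zeros(N_ACTIONS)
            row[grp["c"].to_numpy()] = grp["probability"].to_numpy()
            rows[sit] = row
        return cls(rows)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Strategy)
            and set(self._rows) == set(other._rows)
            and all(np.allclose(r, other._rows[s]) for s, r in self._rows.items())
        )
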