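"""One- and two-parameter sweeps of equilibrium behavior.

Each grid point is an independent, deterministic equilibrium solve; results
are collected into one long-format table (grid values as leading columns),
with per-point convergence flags.  Non-convergence at a point is flagged in
its rows and the sweep continues.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import ModelParameters, SolverControls, validate
from .solver import (
    EquilibriumResult,
    acceptance_table,
    season_aggregated_outcomes,
    solve,
    values_table,
)

logger = logging.getLogger(__name__)

__all__ = ["SweepSpec", "run_sweep", "season_aggregated_acceptance"]

_VALID_OUTPUTS = ("outcomes", "acceptance", "values")
_PARAM_NAMES = {f.name for f in dataclasses.fields(ModelParameters)} | {
    f.name for f in dataclasses.fields(SolverControls)
}


@dataclass(frozen=True)
class SweepSpec:
    """What to sweep and what to report.

    ``parameters`` holds one or two field names of the model parameters;
    ``grids`` the matching value lists (a two-parameter sweep runs the full
    Cartesian product).  ``outputs`` selects any of ``outcomes``,
    ``acceptance``, ``values``; ``aggregation`` is ``season`` or ``per_t``.
    """

    parameters: tuple[str, ...]
    grids: tuple[tuple[float, ...], ...]
    outputs: tuple[str, ...] = ("outcomes",)
    aggregation: str = "season"

    def __post_init__(self):
        if not (1 <= len(self.parameters) <= 2) or len(self.parameters) != len(self.grids):
            raise ValueError("need one or two swept parameters with matching grids")
        for name in self.parameters:
            if name not in _PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r}")
        if any(len(g) == 0 for g in self.grids):
            raise ValueError("empty grid")
        bad = set(self.outputs) - set(_VALID_OUTPUTS)
        if bad:
            raise ValueError(f"unknown output(s): {sorted(bad)}")
        if self.aggregation not in ("season", "per_t"):
            raise ValueError("aggregation must be 'season' or 'per_t'")


def season_aggregated_acceptance(eq: EquilibriumResult) -> pd.DataFrame:
    """Acceptance probability per (male status, female class), weighted by
    the expected number of such encounters in the resident forward pass."""
    tbl = acceptance_table(eq)
    rows = []
    for key, grp in tbl.groupby(["male_status", "female_status", "female_size"], sort=True):
        w = grp["weight"].clip(lower=0.0)
        total = float(w.sum())
        acc = float((grp["acceptance"] * w).sum() / total) if total > 0 else float("nan")
        rows.append(
            dict(
                male_status=key[0],
                female_status=key[1],
                female_size=key[2],
                acceptance=acc,
                weight=total,
            )
        )
    return pd.DataFrame.from_records(rows)


def _point_frame(eq: EquilibriumResult, spec: SweepSpec) -> pd.DataFrame:
    from .solver import outcome_table  # per-t variant

    frames = []
    for kind in spec.outputs:
        if kind == "outcomes":
            df = (
                outcome_table(eq)
                if spec.aggregation == "per_t"
                else season_aggregated_outcomes(eq)
            )
        elif kind == "acceptance":
            df = (
                acceptance_table(eq)
                if spec.aggregation == "per_t"
                else season_aggregated_acceptance(eq)
            )
        else:
            df = values_table(eq)
        df = df.copy()
        df.insert(0, "output", kind)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["converged"] = eq.converged
    out["residual"] = eq.residual
    out["iterations"] = eq.iterations
    return out


def run_sweep(base: ModelParameters, spec: SweepSpec) -> pd.DataFrame:
    """Solve at every grid point; returns one tidy table in deterministic
    row order (grid order, then output kind)."""
    validate(base)
    frames = []
    for values in itertools.product(*spec.grids):
        overrides = dict(zip(spec.parameters, values))
        params = validate(base.replace(**overrides))
        eq = solve(params)
        if not eq.converged:
            logger.warning("grid point %s did not converge (residual %.2e)",
                           overrides, eq.residual)
        df = _point_frame(eq, spec)
        for name, v in reversed(overrides.items()):
            df.insert(0, name, v)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
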