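"""Model parameters, solver controls, validation and flat-file config I/O.

The biological model is parameterized by thirteen scalars (mating-plug
failure probability, maturation and mortality rates, the post-attack
copulation extension, sex ratio, site density, pheromone attractiveness of
virgin vs mated females, the female size structure, season length, and the
decision-error coefficient).  Solver controls (tolerances, iteration caps,
the stored-sperm grid) are numerical plumbing and live in a sub-block.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "SolverControls",
    "ModelParameters",
    "default_parameters",
    "validate",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class SolverControls:
    """Numerical controls for the equilibrium solver (not biology)."""

    convergence_tol: float = 1e-6
    max_iterations: int = 500
    sperm_cap: int = 100
    damping: float = 0.5
    arrival_k_max: int = 7


@dataclass(frozen=True)
class ModelParameters:
    """All biological parameters of the mating-game model.

    Rates and probabilities are per time step; one time step is the time a
    male needs to move between web sites.  Sperm is measured in units of
    one second of copulation (one unit transferred per second).
    """

    #: probability that a copulation into a previously used opening transfers no sperm
    plug: float = 0.8
    #: per-step probability that a subadult male moults to adulthood
    maturation_male: float = 1.0
    #: per-step probability that a subadult female moults to adulthood
    maturation_female: float = 0.5
    #: per-step mortality probability of males
    mortality_male: float = 0.02
    #: per-step mortality probability of females
    mortality_female: float = 0.02
    #: seconds a non-escaping male keeps copulating after the female's attack
    delta_extension: int = 10
    #: initial males per initial female
    sex_ratio: float = 1.0
    #: web sites per initial female
    sites_per_female: float = 1.0
    #: pheromone attractiveness of a virgin-female site relative to an empty site
    attract_virgin: float = 5.0
    #: pheromone attractiveness of a mated-female site relative to an empty site
    attract_mated: float = 1.0
    #: proportion of females that are large
    prop_large: float = 0.5
    #: fecundity of a small female relative to a large one (= 1)
    fecundity_small: float = 0.5
    #: number of time steps in the mating season
    t_max: int = 10
    #: decision-error coefficient: larger values flatten the action distribution
    error_delta: float = 0.1
    #: if True a male attacked before his planned escape still gains the extension
    delta_on_interrupted: bool = True
    #: if True the error function uses an absolute value scale instead of relative
    error_absolute_scale: bool = False
    solver: SolverControls = field(default_factory=SolverControls)

    def replace(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced (solver fields allowed too)."""
        solver_fields = {f.name for f in dataclasses.fields(SolverControls)}
        solver_kw = {k: v for k, v in kwargs.items() if k in solver_fields}
        top_kw = {k: v for k, v in kwargs.items() if k not in solver_fields}
        solver = dataclasses.replace(self.solver, **solver_kw) if solver_kw else self.solver
        return dataclasses.replace(self, solver=solver, **top_kw)


def default_parameters() -> ModelParameters:
    """Default parameter set of the model."""
    return ModelParameters()


_PROBABILITIES = (
    "plug",
    "maturation_male",
    "maturation_female",
    "mortality_male",
    "mortality_female",
    "prop_large",
)
_STRICTLY_POSITIVE = (
    "sites_per_female",
    "attract_virgin",
    "attract_mated",
    "fecundity_small",
)


def validate(params: ModelParameters) -> ModelParameters:
    """Check every invariant; return ``params`` unchanged if all hold.

    Raises
    ------
    ValueError
        naming the first violated invariant.
    """
    for name in _PROBABILITIES:
        v = getattr(params, name)
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v!r}: probability out of range [0, 1]")
    for name in _STRICTLY_POSITIVE:
        v = getattr(params, name)
        if not v > 0:
            raise ValueError(f"{name}={v!r} must be > 0")
    if params.sex_ratio < 0:
        raise ValueError(f"sex_ratio={params.sex_ratio!r} must be >= 0")
    if params.fecundity_small > 1.0:
        raise ValueError(f"fecundity_small={params.fecundity_small!r} must be <= 1")
    if params.t_max < 1:
        raise ValueError("t_max must be >= 1")
    if int(params.t_max) != params.t_max:
        raise ValueError(f"t_max={params.t_max!r} must be an integer")
    if params.delta_extension < 0 or int(params.delta_extension) != params.delta_extension:
        raise ValueError(f"delta_extension={params.delta_extension!r} must be a non-negative integer")
    if not params.error_delta > 0:
        raise ValueError(f"error_delta={params.error_delta!r} must be > 0")
    s = params.solver
    if not s.convergence_tol > 0:
        raise ValueError("convergence_tol must be > 0")
    if s.max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    if not (0.0 <= s.damping < 1.0):
        raise ValueError(f"damping={s.damping!r} must be in [0, 1)")
    if s.arrival_k_max < 1:
        raise ValueError("arrival_k_max must be >= 1")
    if s.sperm_cap < 2 * (10 + params.delta_extension):
        raise ValueError(
            f"sperm_cap={s.sperm_cap!r} must be >= 2*(10 + delta_extension) "
            f"= {2 * (10 + params.delta_extension)}"
        )
    return params


_SOLVER_KEYS = tuple(f.name for f in dataclasses.fields(SolverControls))
_TOP_KEYS = tuple(f.name for f in dataclasses.fields(ModelParameters) if f.name != "solver")
_ALL_KEYS = _TOP_KEYS + _SOLVER_KEYS
_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(ModelParameters)}
_FIELD_TYPES.update({f.name: f.type for f in dataclasses.fields(SolverControls)})


def _coerce(key: str, value):
    ftype = _FIELD_TYPES[key]
    if ftype in ("bool", bool):
        if isinstance(value, bool):
            return value
        raise TypeError(f"{key}: expected a boolean, got {value!r}")
    if ftype in ("int", int):
        if isinstance(value, bool) or int(value) != value:
            raise TypeError(f"{key}: expected an integer, got {value!r}")
        return int(value)
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise TypeError(f"{key}: expected a number, got {value!r}")
    return float(value)


def load_config(path: str | Path) -> ModelParameters:
    """Load parameters from a flat ``key: value`` YAML document.

    Keys are exactly the field names of :class:`ModelParameters` and
    :class:`SolverControls` (solver controls appear at top level).  Missing
    keys fall back to the defaults with a logged notice; unknown keys are an
    error.  The result is validated.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ValueError(f"malformed config {path}{line}: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError(f"malformed config {path}: expected a flat key: value mapping")
    unknown = sorted(set(doc) - set(_ALL_KEYS))
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    missing = [k for k in _ALL_KEYS if k not in doc]
    if missing:
        logger.info("config %s: %d key(s) missing, using defaults: %s",
                    path, len(missing), ", ".join(missing))
    kwargs = {k: _coerce(k, v) for k, v in doc.items()}
    return validate(default_parameters().replace(**kwargs))


def save_config(params: ModelParameters, path: str | Path) -> None:
    """Write parameters as a flat ``key: value`` YAML document (round-trips)."""
    doc = {k: getattr(params, k) for k in _TOP_KEYS}
    doc.update({k: getattr(params.solver, k) for k in _SOLVER_KEYS})
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
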