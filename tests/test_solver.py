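import dataclasses

import numpy as np
import pytest

import monogyny as mg
from monogyny import (
    MATED,
    VIRGIN,
    NoMatingError,
    Situation,
    Strategy,
    acceptance_probability,
    backward_induction,
    outcome_probabilities,
    result_to_dir,
    season_aggregated_outcomes,
    solve,
)
from monogyny.states import enumerate_situations


def test_converges_at_defaults(default_eq):
    assert default_eq.converged
    assert default_eq.residual < default_eq.params.solver.convergence_tol


def test_equilibrium_is_a_fixed_point(default_eq):
    tol = default_eq.params.solver.convergence_tol
    vt = backward_induction(default_eq.env)
    assert default_eq.resident.sup_distance(vt.smoothed) < 10 * tol


def test_equilibrium_independent_of_initial_strategy(default_eq, default_params):
    other = solve(default_params, initial=Strategy.pure_constant(default_params.t_max, 5))
    assert other.converged
    tol = default_params.solver.convergence_tol
    assert default_eq.resident.sup_distance(other.resident) < 10 * tol


def test_outcome_triples_sum_to_one(default_eq):
    for sit in enumerate_situations(default_eq.params.t_max):
        if sit.male_status == VIRGIN and not sit.just_mated:
            triple = outcome_probabilities(default_eq, sit)
            assert sum(triple) == pytest.approx(1.0, abs=1e-9)
            assert min(triple) >= 0.0


def test_certain_death_strategy_is_pure_monogyny1(default_eq):
    rows = {s: default_eq.resident.distribution(s).copy() for s in default_eq.resident.situations}
    sit = Situation(VIRGIN, VIRGIN, mg.LARGE, False, 3)
    row = np.zeros(11)
    row[10] = 1.0
    rows[sit] = row
    fake = dataclasses.replace(default_eq, resident=Strategy(rows))
    triple = outcome_probabilities(fake, sit)
    assert triple.monogyny1 == pytest.approx(1.0)
    assert triple.monogyny2 == triple.bigyny == 0.0


def test_no_mating_conditional_is_flagged(default_eq):
    rows = {s: default_eq.resident.distribution(s).copy() for s in default_eq.resident.situations}
    sit = Situation(VIRGIN, MATED, mg.SMALL, False, 2)
    row = np.zeros(11)
    row[0] = 1.0
    rows[sit] = row
    fake = dataclasses.replace(default_eq, resident=Strategy(rows))
    with pytest.raises(NoMatingError):
        outcome_probabilities(fake, sit)


def test_uniform_row_acceptance_is_ten_elevenths(default_eq):
    fake = dataclasses.replace(
        default_eq, resident=Strategy.uniform(default_eq.params.t_max)
    )
    sit = Situation(VIRGIN, VIRGIN, mg.LARGE, False, 1)
    assert acceptance_probability(fake, sit) == pytest.approx(10 / 11)


def test_mated_males_are_choosier(default_eq):
    """Mated males face certain death upon mating, so they are choosier:
    they reject mated females at least as often as virgin males do at every
    time step, their encounter-weighted rejection rate is higher at every
    step, and the unsmoothed argmax never has a mated male accept a class a
    virgin male rejects.  (On virgin-female classes, where both essentially
    always mate, the error-smoothed probabilities may cross by a few
    percent because the mated male's outside option is worse.)"""
    eq = default_eq
    for t in range(2, eq.params.t_max + 1):
        find = eq.env.record(t).rates.find
        agg = {VIRGIN: 0.0, MATED: 0.0}
        for fs in (VIRGIN, MATED):
            for size in (mg.SMALL, mg.LARGE):
                acc_v = acceptance_probability(eq, Situation(VIRGIN, fs, size, False, t))
                acc_m = acceptance_probability(eq, Situation(MATED, fs, size, False, t))
                if fs == MATED:
                    assert acc_m <= acc_v + 1e-9
                w = find[mg.FemaleClass(size, fs)]
                agg[VIRGIN] += w * acc_v
                agg[MATED] += w * acc_m
                best_v = eq.values.best[Situation(VIRGIN, fs, size, False, t)]
                best_m = eq.values.best[Situation(MATED, fs, size, False, t)]
                assert not (best_m > 0 and best_v == 0)
        assert agg[MATED] <= agg[VIRGIN] + 1e-9


def test_monogyny_concentrates_on_large_virgin_females(default_eq):
    agg = season_aggregated_outcomes(default_eq).set_index(["female_status", "female_size"])
    assert agg.loc[(VIRGIN, mg.LARGE), "bigyny"] <= agg.loc[(MATED, mg.SMALL), "bigyny"]


def test_result_directory_round_trips(default_eq, tmp_path):
    out = result_to_dir(default_eq, tmp_path / "eq")
    for name in (
        "parameters.yaml",
        "strategy.csv",
        "values.csv",
        "acceptance.csv",
        "outcomes.csv",
        "outcomes_aggregated.csv",
        "meta.json",
    ):
        assert (out / name).exists()
    assert mg.load_config(out / "parameters.yaml") == default_eq.params
    import pandas as pd

    restored = Strategy.from_frame(pd.read_csv(out / "strategy.csv"))
    assert restored.sup_distance(default_eq.resident) < 1e-12


def test_nonconvergence_is_reported_not_hidden(default_params):
    p = default_params.replace(max_iterations=2)
    eq = solve(p)
    assert not eq.converged
    assert eq.iterations == 2
    assert eq.residual > p.solver.convergence_tol
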