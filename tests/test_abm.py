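import numpy as np
import pytest

import monogyny as mg
from monogyny import (
    ABMConfig,
    MATED,
    Situation,
    Strategy,
    VIRGIN,
    build_environment,
    backward_induction,
    exhaustive_best_response,
    simulate_abm,
)


def test_same_seed_reproduces_everything(default_params, default_eq):
    cfg = ABMConfig(n_initial_females=2000, seed=42, replicates=2)
    a = simulate_abm(default_params, default_eq.resident, cfg)
    b = simulate_abm(default_params, default_eq.resident, cfg)
    assert a.male_mean_fitness == b.male_mean_fitness
    assert a.class_frequencies.equals(b.class_frequencies)
    assert a.outcomes.equals(b.outcomes)
    c = simulate_abm(default_params, default_eq.resident,
                     ABMConfig(n_initial_females=2000, seed=43, replicates=2))
    assert c.male_mean_fitness != a.male_mean_fitness


def test_reject_everything_means_no_matings(default_params):
    strat = Strategy.pure_constant(default_params.t_max, 0)
    res = simulate_abm(default_params, strat, ABMConfig(n_initial_females=1000, seed=1))
    assert res.male_mean_fitness == 0.0
    assert res.outcomes["matings"].sum() == 0.0
    mated = res.class_frequencies.query("female_status == 'mated'")
    assert (mated["frequency"] == 0.0).all()


def test_class_frequencies_match_mean_field(default_params, default_eq):
    """Finite-population class trajectories agree with the deterministic
    recursions within Monte-Carlo error."""
    res = simulate_abm(
        default_params, default_eq.resident, ABMConfig(n_initial_females=20_000, seed=7, replicates=2)
    )
    for _, row in res.class_frequencies.iterrows():
        rec = default_eq.env.record(int(row.t))
        i = 0 if row.female_size == mg.SMALL else 1
        mf = rec.D[i, 0].sum() if row.female_status == VIRGIN else rec.D[i, 1:].sum()
        assert row.frequency == pytest.approx(mf, abs=max(4 * row.se, 5e-4))


def test_abm_fitness_approaches_dp_value(default_params, default_eq):
    res = simulate_abm(
        default_params, default_eq.resident, ABMConfig(n_initial_females=20_000, seed=5, replicates=3)
    )
    v = default_eq.values.value(VIRGIN, 1)
    assert res.male_mean_fitness == pytest.approx(v, abs=max(4 * res.male_fitness_se, 0.01))


@pytest.fixture(scope="module")
def one_step_env():
    p = mg.default_parameters().replace(t_max=1, error_delta=1e-6, arrival_k_max=2)
    return build_environment(Strategy.uniform(1), p)


def test_exhaustive_oracle_matches_backward_argmax(one_step_env):
    vt = backward_induction(one_step_env)
    optimal = exhaustive_best_response(one_step_env)
    assert set(optimal) == set(mg.enumerate_situations(1))
    for sit, actions in optimal.items():
        assert vt.best[sit] in actions


def test_exhaustive_oracle_second_copulations_are_terminal(one_step_env):
    optimal = exhaustive_best_response(one_step_env)
    for sit, actions in optimal.items():
        if sit.just_mated:
            assert actions == {10}


def test_exhaustive_oracle_all_tie_without_females():
    p = mg.default_parameters().replace(t_max=1, maturation_female=0.0, arrival_k_max=2)
    env = build_environment(Strategy.uniform(1), p)
    optimal = exhaustive_best_response(env)
    for actions in optimal.values():
        assert actions == set(range(11))


def test_exhaustive_oracle_refuses_long_seasons(default_params):
    env = build_environment(Strategy.uniform(2), default_params.replace(t_max=2))
    with pytest.raises(ValueError, match="t_max = 1"):
        exhaustive_best_response(env)


def test_abm_config_validation():
    with pytest.raises(ValueError):
        ABMConfig(n_initial_females=0)
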