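import numpy as np
import pytest

import monogyny as mg
from monogyny import (
    LARGE,
    Openings,
    Strategy,
    build_environment,
    competition_kernel,
    default_parameters,
    expected_gain,
    run_season,
    step_subadults,
)


def test_step_subadults_order_of_operations():
    remaining, new = step_subadults(1.0, 0.5, 0.02)
    assert new == pytest.approx(0.5)
    assert remaining == pytest.approx(0.49)
    assert step_subadults(0.7, 1.0, 0.02)[0] == 0.0  # everyone matures at once
    assert step_subadults(0.7, 0.0, 0.0) == (0.7, 0.0)


def test_trajectory_length_and_record_count():
    p = default_parameters()
    season = run_season(Strategy.uniform(p.t_max), p)
    assert len(season.records) == p.t_max
    assert len(season.trajectory) == p.t_max + 1
    assert season.record(1).t == 1 and season.record(p.t_max).t == p.t_max


def test_no_interactions_no_deaths_conserves_everything():
    p = default_parameters().replace(mortality_male=0.0, mortality_female=0.0)
    season = run_season(Strategy.pure_constant(p.t_max, 0), p)
    for state in season.trajectory[1:]:
        total_f = state.subadult_females + state.total_adult_females()
        assert total_f == pytest.approx(1.0, abs=1e-12)
        # nobody copulates, so every adult female stays a virgin with no sperm
        assert state.females[:, 1:].sum() == 0.0
        assert state.females[:, :, 1:].sum() == 0.0


def test_female_mass_decays_at_mortality_rate():
    p = default_parameters()
    season = run_season(Strategy.uniform(p.t_max), p)
    for t, state in enumerate(season.trajectory[1:], start=1):
        total_f = state.subadult_females + state.total_adult_females()
        # mortality applies after every step except the last (oviposition)
        expected = (1.0 - p.mortality_female) ** min(t, p.t_max - 1)
        assert total_f == pytest.approx(expected, abs=1e-10)


def test_no_males_means_no_matings():
    p = default_parameters().replace(sex_ratio=0.0)
    season = run_season(Strategy.uniform(p.t_max), p)
    for state in season.trajectory:
        assert state.females[:, 1:].sum() == 0.0  # all virgin throughout


def test_all_males_adult_at_first_step():
    p = default_parameters()
    season = run_season(Strategy.uniform(p.t_max), p)
    assert season.trajectory[1].subadult_males == 0.0


def test_virgin_mass_non_increasing_without_maturation():
    p = default_parameters().replace(maturation_female=0.0)
    season = run_season(Strategy.uniform(p.t_max), p)
    virgin = [s.females[:, 0].sum() for s in season.trajectory]
    assert all(b <= a + 1e-12 for a, b in zip(virgin, virgin[1:]))


def test_sperm_bookkeeping_matches_step_records():
    p = default_parameters()
    season = run_season(Strategy.uniform(p.t_max), p)
    y = np.arange(p.solver.sperm_cap + 1)
    for t in range(1, p.t_max):
        before = float((season.trajectory[t - 1].females * y).sum())
        rec = season.record(t)
        matured_sperm = 0.0  # new adults carry none
        after_mating = before + matured_sperm + rec.sperm_added
        after_mort = after_mating * (1 - p.mortality_female)
        actual = float((season.trajectory[t].females * y).sum())
        assert actual == pytest.approx(after_mort, abs=1e-9)


def test_perfect_plug_blocks_used_opening_transfer():
    """With plug = 1 a female can receive at most one transfer per opening,
    so stored sperm never exceeds two full copulations' worth."""
    p = default_parameters().replace(plug=1.0)
    season = run_season(Strategy.uniform(p.t_max), p)
    cap_two_cops = 2 * (10 + p.delta_extension)
    for state in season.trajectory:
        assert state.females[:, :, cap_two_cops + 1 :].sum() == pytest.approx(0.0, abs=1e-12)


def test_site_shortage_defers_maturation():
    p = default_parameters().replace(sites_per_female=0.5)
    season = run_season(Strategy.uniform(p.t_max), p)
    for state in season.trajectory:
        assert state.total_adult_females() <= 0.5 + 1e-12


def test_kernel_boundary_and_mass():
    p = default_parameters()
    season = run_season(Strategy.uniform(p.t_max), p)
    K = competition_kernel(season)
    t_max = p.t_max
    assert np.allclose(K[t_max, :, :, 0], 1.0)
    assert K[t_max, :, :, 1:].sum() == 0.0
    for t in range(1, t_max + 1):
        assert K[t].sum(axis=-1).max() <= 1.0 + 1e-12


def test_kernel_closed_form_without_males():
    p = default_parameters().replace(sex_ratio=0.0)
    season = run_season(Strategy.uniform(p.t_max), p)
    K = competition_kernel(season)
    for t in range(1, p.t_max + 1):
        expected = (1 - p.mortality_female) ** (p.t_max - t)
        assert np.allclose(K[t, :, :, 0], expected)
        assert K[t, :, :, 1:].sum() == pytest.approx(0.0, abs=1e-15)


def test_expected_gain_survival_only_closed_form():
    """A sole lifetime mate: the gain from any positive transfer is her
    survival probability to oviposition times her fecundity."""
    p = default_parameters().replace(sex_ratio=0.0)
    env = build_environment(Strategy.uniform(p.t_max), p)
    for t in (1, 4, p.t_max):
        g = expected_gain(5, LARGE, Openings.VIRGIN, Openings.HALF_PLUGGED, t, env)
        assert g == pytest.approx((1 - p.mortality_female) ** (p.t_max - t))
    assert expected_gain(0, LARGE, Openings.VIRGIN, Openings.HALF_PLUGGED, 1, env) == 0.0


def test_negative_mass_raises():
    p = default_parameters()
    pop = mg.PopulationState.initial(p)
    pop.males_virgin = -0.5
    with pytest.raises(RuntimeError, match="negative"):
        pop.check()
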