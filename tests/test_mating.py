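import numpy as np
import pytest

from monogyny import (
    Openings,
    default_parameters,
    expected_sperm,
    opening_used_probability,
    outcome_distribution,
    survival_probability,
)


def enumerate_expected_sperm(c, used, params):
    """Independent enumeration over attack ticks and the plug lottery."""
    if c == 0:
        return 0.0
    total = 0.0
    keep = (1.0 - params.plug) if used else 1.0
    if c < 10:
        total += (1.0 - c / 10.0) * c * keep
    for attack in range(1, c + 1):
        gets_delta = params.delta_on_interrupted or c == 10
        total += 0.1 * (attack + (params.delta_extension if gets_delta else 0)) * keep
    return total


@pytest.mark.parametrize("c", range(11))
def test_survival_law_is_linear(c):
    assert survival_probability(c) == pytest.approx(1.0 - c / 10.0, abs=0)


def test_survival_rejects_out_of_range():
    for c in (-1, 11, 2.5):
        with pytest.raises(ValueError):
            survival_probability(c)


def test_outcome_distribution_unused_opening_example():
    p = default_parameters()
    d = outcome_distribution(3, False, p)
    assert d.probability(survived=True) == pytest.approx(0.7)
    assert d.probability(survived=True, sperm_transferred=3) == pytest.approx(0.7)
    for sperm in (11, 12, 13):
        assert d.probability(survived=False, sperm_transferred=sperm) == pytest.approx(0.1)


def test_outcome_distribution_degenerate_and_fatal_cases():
    p = default_parameters()
    d0 = outcome_distribution(0, True, p)
    assert d0.items == [(d0.items[0][0], 1.0)] and d0.items[0][0].sperm_transferred == 0
    assert d0.items[0][0].survived
    # full-duration copulation into a used opening: always fatal, plug may void it
    d10 = outcome_distribution(10, True, p)
    assert d10.probability(survived=True) == 0.0
    assert d10.probability(sperm_transferred=0) == pytest.approx(0.8)
    for attack in range(1, 11):
        assert d10.probability(sperm_transferred=attack + 10) == pytest.approx(0.02)


@pytest.mark.parametrize(
    "c, used, expected",
    [(10, False, 15.5), (3, False, 5.7), (10, True, 3.1)],
)
def test_expected_sperm_closed_forms(c, used, expected):
    p = default_parameters()
    assert expected_sperm(c, used, p) == pytest.approx(expected)
    assert expected_sperm(c, used, p) == pytest.approx(enumerate_expected_sperm(c, used, p))


@pytest.mark.parametrize("used", [False, True])
@pytest.mark.parametrize("c", range(11))
def test_distribution_invariants(c, used):
    p = default_parameters()
    d = outcome_distribution(c, used, p)
    assert sum(pr for _, pr in d.items) == pytest.approx(1.0, abs=1e-12)
    assert all(o.sperm_transferred <= 10 + p.delta_extension for o, _ in d.items)
    assert d.survival() == pytest.approx(survival_probability(c))
    assert d.expected_sperm() == pytest.approx(enumerate_expected_sperm(c, used, p))


def test_expected_sperm_strictly_increasing_unused():
    p = default_parameters()
    vals = [expected_sperm(c, False, p) for c in range(11)]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_unit_slope_conditional_on_escape():
    """Sperm transfer is one unit per second while the male is alive: the
    escape outcome of a c-second attempt carries exactly c units."""
    p = default_parameters()
    for c in range(1, 10):
        d = outcome_distribution(c, False, p)
        esc = [o for o, _ in d.items if o.survived]
        assert len(esc) == 1 and esc[0].sperm_transferred == c


def test_plug_zero_equates_openings():
    p = default_parameters().replace(plug=0.0)
    for c in range(11):
        a = outcome_distribution(c, False, p)
        b = outcome_distribution(c, True, p)
        assert [(o.survived, o.sperm_transferred, pr) for o, pr in a.items] == [
            (o.survived, o.sperm_transferred, pr) for o, pr in b.items
        ]


def test_extension_only_for_committed_males_when_switched():
    p = default_parameters().replace(delta_on_interrupted=False)
    d = outcome_distribution(3, False, p)
    killed = sorted(o.sperm_transferred for o, _ in d.items if not o.survived)
    assert killed == [1, 2, 3]  # attack time only, no extension
    d10 = outcome_distribution(10, False, p)
    assert max(o.sperm_transferred for o, _ in d10.items) == 20  # c=10 keeps it


@pytest.mark.parametrize(
    "context, openings, first_hit, expected",
    [
        ("virgin_male_first", Openings.VIRGIN, None, 0.0),
        ("mated_male_unrelated", Openings.HALF_PLUGGED, None, 0.5),
        ("mated_male_unrelated", Openings.FULLY_PLUGGED, None, 1.0),
        ("same_female_second", Openings.VIRGIN, None, 0.0),
        ("same_female_second", Openings.FULLY_PLUGGED, None, 1.0),
        ("same_female_second", Openings.HALF_PLUGGED, True, 0.0),
        ("same_female_second", Openings.HALF_PLUGGED, False, 1.0),
    ],
)
def test_opening_resolution(context, openings, first_hit, expected):
    assert opening_used_probability(context, openings, first_hit) == expected


def test_opening_resolution_requires_first_side_when_ambiguous():
    with pytest.raises(ValueError, match="first_copulation_hit_used"):
        opening_used_probability("same_female_second", Openings.HALF_PLUGGED)
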