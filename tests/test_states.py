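import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from monogyny import (
    LARGE,
    MATED,
    SMALL,
    VIRGIN,
    FemaleClass,
    FemaleState,
    Openings,
    Situation,
    Strategy,
    enumerate_situations,
    perceive,
)


def brute_force_situations(t_max):
    """Independent reachability filter over the full factor product."""
    out = []
    for t in range(1, t_max + 1):
        for jm in (False, True):
            for ms in (VIRGIN, MATED):
                for fs in (VIRGIN, MATED):
                    for size in (SMALL, LARGE):
                        if jm and ms == VIRGIN:
                            continue  # a just-mated male has used a pedipalp
                        if t == 1:
                            # females first mature within step 1 and all males
                            # arrive simultaneously: every arrival is at a
                            # virgin female, and no male is mated beforehand
                            if fs == MATED or (not jm and ms == MATED):
                                continue
                        out.append((ms, fs, size, jm, t))
    return out


@pytest.mark.parametrize("t_max", list(range(1, 13)))
def test_situation_count_matches_formula_and_brute_force(t_max):
    sits = enumerate_situations(t_max)
    assert len(sits) == 12 * t_max - 8
    assert len(sits) == len(set(sits))
    assert {tuple(s) for s in sits} == set(brute_force_situations(t_max))


def test_situation_count_examples():
    assert len(enumerate_situations(10)) == 112
    assert len(enumerate_situations(1)) == 4
    assert len(enumerate_situations(2)) == 16


def test_enumeration_order_deterministic():
    assert enumerate_situations(5) == enumerate_situations(5)
    with pytest.raises(ValueError):
        enumerate_situations(0)


def test_perceive_examples():
    assert perceive(FemaleState(LARGE, True, False, 7)) == FemaleClass(LARGE, MATED)
    assert perceive(FemaleState(SMALL, False, False, 0)) == FemaleClass(SMALL, VIRGIN)
    # fully plugged with zero transfer is still perceived as mated
    assert perceive(FemaleState(SMALL, True, True, 0)) == FemaleClass(SMALL, MATED)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    size=st.sampled_from([SMALL, LARGE]),
    used=st.sampled_from([(False, False), (True, False), (False, True), (True, True)]),
    sperm=st.integers(min_value=0, max_value=100),
)
def test_perceive_is_a_projection(size, used, sperm):
    """Females differing only in stored sperm or in which opening was used
    are indistinguishable to a male."""
    if used == (False, False):
        sperm = 0
    f = FemaleState(size, used[0], used[1], sperm)
    cls = perceive(f)
    assert cls.size == size
    assert (cls.status == VIRGIN) == (f.openings is Openings.VIRGIN)
    mirrored = FemaleState(size, used[1], used[0], sperm)
    assert perceive(mirrored) == cls
    if sperm > 0:
        assert perceive(FemaleState(size, used[0], used[1], sperm - 1)) == cls


def test_virgin_female_cannot_store_sperm():
    with pytest.raises(ValueError):
        FemaleState(SMALL, False, False, 3)


def test_strategy_round_trip_and_mixing():
    s = Strategy.uniform(3)
    assert len(s.situations) == 12 * 3 - 8
    frame = s.to_frame()
    assert Strategy.from_frame(frame) == s
    t = Strategy.pure_constant(3, 10)
    mixed = s.mix(t, 0.5)
    sit = s.situations[0]
    assert mixed.distribution(sit)[10] == pytest.approx(0.5 / 11 + 0.5)
    assert s.sup_distance(t) == pytest.approx(1.0 - 1.0 / 11)
    assert t.pure() == t
    assert mixed.pure().argmax_action(sit) == 10


def test_strategy_rejects_bad_rows():
    sit = Situation(VIRGIN, VIRGIN, SMALL, False, 1)
    with pytest.raises(ValueError):
        Strategy({sit: np.ones(11)})
    with pytest.raises(ValueError):
        Strategy({sit: np.ones(5) / 5})
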