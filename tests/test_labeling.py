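"""Risk labeler: analytic extremes, brute-force oracle, range/monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cfirs import ParameterError, feature_contribution, irs_from_contributions, label_profiles
from cfirs.labeling import DegenerateRangeError
from cfirs.matrix import StructuralError

from conftest import make_indicators


# ------------------------------------------------------- feature_contribution

def test_extremes_and_direction_flip():
    assert feature_contribution(5.0, 1.0, 5.0, 1) == 1.0
    assert feature_contribution(1.0, 1.0, 5.0, 1) == 0.0
    assert feature_contribution(1.0, 1.0, 5.0, -1) == 1.0
    assert feature_contribution(5.0, 1.0, 5.0, -1) == 0.0


def test_midpoint_is_half_either_direction():
    assert feature_contribution(3.0, 1.0, 5.0, 1) == pytest.approx(0.5)
    assert feature_contribution(3.0, 1.0, 5.0, -1) == pytest.approx(0.5)


def test_degenerate_range_rejected():
    with pytest.raises(DegenerateRangeError):
        feature_contribution(1.0, 2.0, 2.0, 1)


@given(
    x=st.floats(-1e6, 1e6),
    lo=st.floats(-100, 100),
    width=st.floats(1e-3, 100),
    direction=st.sampled_from([1, -1]),
)
@settings(max_examples=200, deadline=None)
def test_contribution_always_in_unit_interval(x, lo, width, direction):
    y = feature_contribution(x, lo, lo + width, direction)
    assert 0.0 <= y <= 1.0


@given(
    lo=st.floats(-10, 10),
    width=st.floats(0.1, 10),
    frac=st.floats(0, 1),
)
@settings(max_examples=100, deadline=None)
def test_direction_flip_is_an_involution(lo, width, frac):
    x = lo + frac * width
    up = feature_contribution(x, lo, lo + width, 1)
    down = feature_contribution(x, lo, lo + width, -1)
    assert up + down == pytest.approx(1.0, abs=1e-12)


def test_monotone_in_expression():
    xs = np.linspace(0.0, 10.0, 50)
    up = feature_contribution(xs, 0.0, 10.0, 1)
    down = feature_contribution(xs, 0.0, 10.0, -1)
    assert np.all(np.diff(up) >= 0)
    assert np.all(np.diff(down) <= 0)


# ------------------------------------------------------- IRS aggregation

def test_irs_of_unit_and_zero_vectors():
    assert irs_from_contributions(np.ones(7)) == 1.0
    assert irs_from_contributions(np.zeros(7)) == 0.0


def test_irs_is_plain_mean():
    assert irs_from_contributions(np.array([0.2, 0.4, 0.9])) == pytest.approx(0.5)


def test_irs_rejects_empty_vector():
    with pytest.raises(ParameterError):
        irs_from_contributions(np.array([]))


# ------------------------------------------------------- label_profiles

def test_risk_extreme_profile_scores_exactly_one(toy_indicators):
    lo, hi = toy_indicators.bounds
    d = toy_indicators.directions
    profile = np.where(d == 1, hi, lo)
    y, irs = label_profiles(profile[None, :], toy_indicators)
    assert np.all(y == 1.0)
    assert irs[0] == 1.0
    opposite = np.where(d == 1, lo, hi)
    _, irs0 = label_profiles(opposite[None, :], toy_indicators)
    assert irs0[0] == 0.0


def test_identical_profiles_identical_irs(toy_indicators):
    rng = np.random.default_rng(0)
    lo, hi = toy_indicators.bounds
    p = rng.uniform(lo, hi)
    _, irs = label_profiles(np.vstack([p, p]), toy_indicators)
    assert irs[0] == irs[1]


def test_matches_per_feature_bruteforce(toy_indicators):
    rng = np.random.default_rng(1)
    lo, hi = toy_indicators.bounds
    d = toy_indicators.directions
    x = rng.uniform(lo, hi, size=(20, lo.size))
    y, irs = label_profiles(x, toy_indicators)
    for r in range(x.shape[0]):
        for i in range(lo.size):
            raw = (x[r, i] - lo[i]) / (hi[i] - lo[i])
            expected = raw if d[i] == 1 else 1.0 - raw
            assert y[r, i] == pytest.approx(expected, abs=1e-12)
        assert irs[r] == pytest.approx(np.mean(y[r]), abs=1e-15)


def test_out_of_bounds_inputs_are_clipped(toy_indicators):
    lo, hi = toy_indicators.bounds
    below = lo - 100.0
    above = hi + 100.0
    y_lo, _ = label_profiles(below[None, :], toy_indicators)
    y_hi, _ = label_profiles(above[None, :], toy_indicators)
    assert set(np.unique(y_lo)) <= {0.0, 1.0}
    assert set(np.unique(y_hi)) <= {0.0, 1.0}


def test_per_batch_bounds_use_the_batch_extremes(toy_indicators):
    rng = np.random.default_rng(2)
    x = rng.uniform(size=(10, len(toy_indicators))) * 5.0
    y, _ = label_profiles(x, toy_indicators, bound_source="per-batch")
    # with per-batch bounds every column attains both 0 and 1
    assert np.all(y.min(axis=0) == 0.0)
    assert np.all(y.max(axis=0) == 1.0)


def test_column_mismatch_raises(toy_indicators):
    with pytest.raises(StructuralError):
        label_profiles(np.zeros((3, 2)), toy_indicators)


def test_increasing_one_feature_moves_irs_with_direction():
    ind = make_indicators(lo=[0.0, 0.0], hi=[1.0, 1.0], direction=[1, -1])
    base = np.array([[0.5, 0.5]])
    _, irs_base = label_profiles(base, ind)
    _, irs_up0 = label_profiles(np.array([[0.8, 0.5]]), ind)
    _, irs_up1 = label_profiles(np.array([[0.5, 0.8]]), ind)
    assert irs_up0[0] > irs_base[0]   # direction +1: raising x raises IRS
    assert irs_up1[0] < irs_base[0]   # direction -1: raising x lowers IRS
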