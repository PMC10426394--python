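"""Filtration primitives against independent oracles, and pipeline behaviour."""

import itertools
import math

import numpy as np
import pytest

from cfirs import (
    CohortParams,
    FilterParams,
    NoIndicatorsError,
    ParameterError,
    generate_cohort,
    select_indicators,
)
from cfirs.filtration import (
    drop_zero_features,
    group_difference_test,
    overlap_coefficient,
    standardized_mean_deviation,
)
from cfirs.matrix import ExpressionMatrix, StructuralError


# ---------------------------------------------------------------- overlap

@pytest.mark.parametrize(
    "sp, sn, expected",
    [
        ([0, 5], [0, 5], 1.0),             # identical domains
        ([0, 1], [2, 3], 0.0),             # disjoint
        ([1, 3], [2, 4], 1.0 / 3.0),       # intersection 1 over union 3
        ([2, 2], [2, 2], 1.0),             # equal point ranges
        ([2, 2], [3, 3], 0.0),             # distinct point ranges
        ([2, 2], [1, 3], 0.0),             # point inside a range has zero length
        ([1, 10], [2, 3], 1.0 / 9.0),      # containment
    ],
)
def test_overlap_coefficient_interval_arithmetic(sp, sn, expected):
    assert overlap_coefficient(np.array(sp), np.array(sn)) == pytest.approx(expected)


def test_overlap_rejects_empty_sets():
    with pytest.raises(ParameterError):
        overlap_coefficient(np.array([]), np.array([1.0]))


# ---------------------------------------------------------------- SMD

def test_smd_zero_for_identical_sets():
    x = np.array([1.0, 2.0, 5.0])
    assert standardized_mean_deviation(x, x) == 0.0


def test_smd_infinite_for_separated_point_masses():
    assert standardized_mean_deviation(np.array([2.0, 2.0]), np.array([0.0, 0.0])) == math.inf


def test_smd_matches_direct_formula():
    sp = np.array([1.0, 2.0, 3.0])
    sn = np.array([4.0, 5.0, 6.0])
    pooled_sd = math.sqrt((2 * np.var(sp, ddof=1) + 2 * np.var(sn, ddof=1)) / 4)
    expected = abs(sp.mean() - sn.mean()) / pooled_sd
    assert standardized_mean_deviation(sp, sn) == pytest.approx(expected)


# ---------------------------------------------------------------- MWU test

def _exact_two_sided_p(sp, sn):
    """Brute-force two-sided Mann-Whitney p by full enumeration."""
    pooled = np.concatenate([sp, sn])
    n1 = len(sp)
    ranks = np.argsort(np.argsort(pooled)) + 1  # no ties by construction
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        r = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        us.append(r)
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


def test_identical_groups_give_p_near_one():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    assert group_difference_test(x, x) > 0.9


def test_exact_p_matches_enumeration_oracle():
    rng = np.random.default_rng(42)
    for _ in range(5):
        sp = rng.normal(1.0, 1.0, size=5)
        sn = rng.normal(0.0, 1.0, size=4)
        assert group_difference_test(sp, sn) == pytest.approx(
            _exact_two_sided_p(sp, sn), abs=1e-12
        )


def test_complete_separation_tail_probability():
    """All PE above all NP at n=10 vs 10 gives the exact rank-sum tail."""
    sp = np.arange(11.0, 21.0)
    sn = np.arange(1.0, 11.0)
    expected = 2.0 / math.comb(20, 10)
    assert group_difference_test(sp, sn) == pytest.approx(expected, rel=1e-9)


def test_planted_effect_detected_across_seeds():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        sn = rng.lognormal(1.0, 1.0, size=30)
        sp = rng.lognormal(4.0, 1.0, size=30)  # shift of 3 on the log scale
        hits += group_difference_test(sp, sn) < 0.01
    assert hits >= 95


def test_too_few_values_rejected():
    with pytest.raises(ParameterError):
        group_difference_test(np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0]))


# ---------------------------------------------------------------- zero drop

def test_drop_zero_features_rules():
    ids = ["a", "b", "c"]
    np_m = ExpressionMatrix(np.array([[0, 0], [0, 0], [1, 2]]), ids, ["n1", "n2"])
    pe_m = ExpressionMatrix(np.array([[0, 0], [0, 3], [4, 5]]), ids, ["p1", "p2"])
    mask = drop_zero_features(np_m, pe_m)
    # all-zero in both groups -> excluded; zero in NP but positive in one PE
    # sample -> retained
    np.testing.assert_array_equal(mask, [False, True, True])


def test_drop_zero_count_matches_cohort_fraction():
    np_m, pe_m, _ = generate_cohort(
        CohortParams(n_features=100, frac_zero=0.2, frac_informative=0.1, seed=2)
    )
    mask = drop_zero_features(np_m, pe_m)
    assert (~mask).sum() == 20


def test_drop_zero_requires_shared_features():
    a = ExpressionMatrix(np.ones((2, 2)), ["x", "y"], ["s1", "s2"])
    b = ExpressionMatrix(np.ones((2, 2)), ["x", "z"], ["s3", "s4"])
    with pytest.raises(StructuralError):
        drop_zero_features(a, b)


# ---------------------------------------------------------------- selection

def test_null_cohort_yields_no_indicators():
    np_m, pe_m, _ = generate_cohort(
        CohortParams(n_features=300, frac_informative=0.0, effect_size=0.0, seed=4)
    )
    with pytest.raises(NoIndicatorsError, match="no"):
        select_indicators(np_m, pe_m)


def test_selected_indicators_are_mostly_planted(small_cohort, small_indicators):
    _, _, truth = small_cohort
    selected = set(small_indicators.feature_ids)
    planted = set(truth.informative_ids)
    precision = len(selected & planted) / len(selected)
    assert precision >= 0.8


def test_selection_invariant_to_sample_order(small_cohort, small_indicators):
    np_m, pe_m, _ = small_cohort
    rng = np.random.default_rng(0)

    def shuffled(m):
        order = rng.permutation(m.n_samples)
        return ExpressionMatrix(
            m.values[:, order], m.feature_ids, [m.sample_ids[i] for i in order]
        )

    permuted = select_indicators(shuffled(np_m), shuffled(pe_m))
    assert permuted.feature_ids == small_indicators.feature_ids
    np.testing.assert_allclose(
        permuted.table.to_numpy(), small_indicators.table.to_numpy()
    )


def test_loosening_alpha_never_shrinks_selection(small_cohort):
    np_m, pe_m, _ = small_cohort
    tight = select_indicators(np_m, pe_m, FilterParams(alpha=0.01))
    loose = select_indicators(np_m, pe_m, FilterParams(alpha=0.10))
    assert set(tight.feature_ids) <= set(loose.feature_ids)


def test_selection_ordered_by_adjusted_p(small_indicators):
    p = small_indicators.table["p_adj"].to_numpy()
    assert np.all(np.diff(p) >= 0)


def test_direction_consistent_with_group_means(small_indicators):
    t = small_indicators.table
    expected = np.where(t["mean_sp"] > t["mean_sn"], 1, -1)
    np.testing.assert_array_equal(t["direction"].to_numpy(), expected)


def test_indicator_set_roundtrips_tsv(tmp_path, small_indicators):
    path = tmp_path / "ind.tsv"
    small_indicators.write_tsv(path)
    from cfirs.filtration import IndicatorSet

    loaded = IndicatorSet.read_tsv(path)
    assert loaded.feature_ids == small_indicators.feature_ids
    np.testing.assert_allclose(
        loaded.table.to_numpy(), small_indicators.table.to_numpy(), rtol=1e-12
    )
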