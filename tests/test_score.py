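"""MIPSS-R combination, quintile classification, bin/weight derivation and
risk migration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mipssr.score import (
    DEFAULT_BINS,
    DEFAULT_WEIGHTS,
    MIPSSR_CATEGORIES,
    MIPSSRWeights,
    QuintileBins,
    classify_mipssr,
    compare_stratifications,
    derive_bins,
    mipssr_score,
    round_half_up,
)


@pytest.mark.parametrize(
    "points,ipssr,display,category",
    [
        (0, 2.0, 1.28, "very_low"),
        (3, 8.5, 8.59, "very_high"),
        (0, 0.0, 0.00, "very_low"),
        (1, 4.5, 3.93, "low"),
        (0, 3.5, 2.24, "very_low"),
        (2, 3.5, 4.34, "intermediate"),
        (2, 5.5, 5.62, "very_high"),
    ],
)
def test_score_formula_and_display(points, ipssr, display, category):
    res = mipssr_score(points, ipssr)
    assert res.score == pytest.approx(1.047 * points + 0.641 * ipssr)
    assert res.score_display == display
    assert res.category == category


@pytest.mark.parametrize(
    "x,expected", [(1.285, 1.29), (0.3205, 0.32), (-1.285, -1.29), (1.282, 1.28)]
)
def test_round_half_away_from_zero(x, expected):
    assert round_half_up(x) == expected


def test_default_weights_and_thresholds():
    assert (DEFAULT_WEIGHTS.coef_mut, DEFAULT_WEIGHTS.coef_ipssr) == (1.047, 0.641)
    assert DEFAULT_BINS.thresholds == pytest.approx((2.285, 3.975, 4.455, 5.460))


def test_grid_closure_contains_all_published_endpoints():
    """Every published per-group range endpoint is an achievable score
    m*1.047 + r*0.641 on the mutation x IPSS-R grid (84 points)."""
    grid = {
        round_half_up(1.047 * m + 0.641 * r)
        for m in range(4)
        for r in np.arange(0, 10.5, 0.5)
    }
    endpoints = [v for lo_hi in DEFAULT_BINS.ranges for v in lo_hi]
    assert all(v in grid for v in endpoints)


def test_published_endpoints_classify_into_their_own_group():
    for category, (lo, hi) in zip(MIPSSR_CATEGORIES, DEFAULT_BINS.ranges):
        assert classify_mipssr(lo) == category
        assert classify_mipssr(hi) == category


def test_classification_clamps_and_rejects_nonfinite():
    assert classify_mipssr(0.0) == "very_low"
    assert classify_mipssr(100.0) == "very_high"
    for bad in (float("nan"), float("inf")):
        with pytest.raises(ValueError):
            classify_mipssr(bad)


def test_classification_uses_full_precision_not_display():
    # just above the very_low/low threshold but displays as the threshold
    assert classify_mipssr(2.2851) == "low"
    assert classify_mipssr(2.2849) == "very_low"


def test_weights_must_be_finite():
    with pytest.raises(ValueError):
        MIPSSRWeights(coef_mut=float("nan"))


def test_bins_must_be_ordered():
    with pytest.raises(ValueError):
        QuintileBins(ranges=((0, 2), (1.5, 3), (4, 5), (6, 7), (8, 9)))
    with pytest.raises(ValueError):
        QuintileBins(ranges=((0, 1), (2, 3)))


def test_derive_bins_uniform_grid():
    bins = derive_bins(np.arange(1, 101, dtype=float))
    assert bins.ranges == ((1, 20), (21, 40), (41, 60), (61, 80), (81, 100))


def test_derive_bins_degenerate_inputs():
    with pytest.raises(ValueError):
        derive_bins([3.0] * 50)
    with pytest.raises(ValueError):
        derive_bins([1.0, 2.0, 3.0, 4.0])


def test_derive_bins_round_trips_with_classification():
    rng = np.random.default_rng(42)
    scores = rng.uniform(1.28, 8.59, size=500)
    bins = derive_bins(scores)
    qs = np.quantile(scores, [0.2, 0.4, 0.6, 0.8])
    groups = np.searchsorted(qs, scores, side="left")
    cats = np.array([classify_mipssr(s, bins) for s in scores])
    expected = np.array(MIPSSR_CATEGORIES)[groups]
    assert (cats == expected).all()


@settings(derandomize=True, max_examples=200)
@given(
    m1=st.integers(0, 3),
    m2=st.integers(0, 3),
    r1=st.integers(0, 20),
    r2=st.integers(0, 20),
)
def test_score_monotone_in_both_inputs(m1, m2, r1, r2):
    """With positive weights the score never decreases when either the
    mutation points or the IPSS-R half-point total increases."""
    if m1 <= m2 and r1 <= r2:
        a = mipssr_score(m1, r1 * 0.5)
        b = mipssr_score(m2, r2 * 0.5)
        assert a.score <= b.score + 1e-12
        order = {c: i for i, c in enumerate(MIPSSR_CATEGORIES)}
        assert order[a.category] <= order[b.category]


@settings(derandomize=True, max_examples=200)
@given(st.floats(min_value=-20, max_value=20, allow_nan=False))
def test_classification_total_over_score_line(score):
    assert classify_mipssr(score) in MIPSSR_CATEGORIES


def test_migration_toy_by_hand():
    a = ["very_low", "intermediate", "very_high"]
    b = ["low", "intermediate", "high"]
    table = compare_stratifications(a, b)
    assert (table.elevated, table.unchanged, table.decreased) == (1, 1, 1)
    assert table.crosstab.to_numpy().sum() == 3


def test_migration_identical_is_all_unchanged():
    a = ["low"] * 10
    table = compare_stratifications(a, a)
    assert table.unchanged == 10
    assert table.pct_changed == 0.0


def test_migration_published_arithmetic():
    """15 decreased and 16 elevated of 54 give 27.78% / 29.63% and a
    57.41% total change rate."""
    a = ["intermediate"] * 54
    b = ["low"] * 15 + ["high"] * 16 + ["intermediate"] * 23
    table = compare_stratifications(a, b)
    assert (table.decreased, table.elevated, table.n) == (15, 16, 54)
    assert table.pct_decreased == 27.78
    assert table.pct_elevated == 29.63
    assert table.pct_changed == 57.41


def test_migration_rejects_unknown_labels():
    with pytest.raises(ValueError, match="unmapped"):
        compare_stratifications(["low"], ["ultra_high"])
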