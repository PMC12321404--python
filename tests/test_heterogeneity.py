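"""Heterogeneity indices against a brute-force pair-enumeration oracle,
plus BCa bootstrap behavior."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methet.heterogeneity import (
    _bca_percentiles,
    bootstrap_mean_ci,
    dichotomize_hi,
    expected_hi_dirichlet_multinomial,
    ki67_intratumoral_hi,
    ki67_patient_hi,
    pair_discordance_oracle,
    subtype_hi,
)


@pytest.mark.parametrize(
    "counts, expected",
    [
        ({"a": 4}, 0.0),
        ({"a": 1, "b": 1}, 100.0),
        ({"a": 3, "b": 1}, 50.0),        # 3 of C(4,2)=6 pairs discordant
        ({"a": 2, "b": 2}, 100 * 4 / 6),  # 4 of 6 pairs discordant
    ],
)
def test_subtype_hi_examples(counts, expected):
    res = subtype_hi(counts)
    assert res.defined
    assert res.value == pytest.approx(expected)


def test_subtype_hi_undefined_below_two_samples():
    res = subtype_hi({"a": 1})
    assert not res.defined and res.value is None and res.n_pairs == 0


def test_subtype_hi_rejects_negative_counts():
    with pytest.raises(ValueError):
        subtype_hi({"a": -1, "b": 3})


@pytest.mark.parametrize(
    "values, expected",
    [
        ([5, 10, 15], 0.0),
        ([10, 80], 100.0),
        ([10, 30, 50, 15], 100 * 4 / 6),   # n_low=2, n_high=2
        ([20, 21], 100.0),                 # 20 is low (<=20), 21 is high
    ],
)
def test_ki67_patient_hi_examples(values, expected):
    assert ki67_patient_hi(values).value == pytest.approx(expected)


def test_ki67_intratumoral_pooling():
    res = ki67_intratumoral_hi({"b1": [10, 50], "b2": [30, 30]})
    assert res.value == pytest.approx(50.0)  # 1 discordant of 2 pooled pairs
    assert ki67_intratumoral_hi({"b1": [10, 10, 10]}).value == 0.0
    assert not ki67_intratumoral_hi({"b1": [5], "b2": [90]}).defined


def test_ki67_intratumoral_average_option():
    # pooled: (1 + 0) / (1 + 3); averaged: mean(100, 0)
    blocks = {"b1": [10, 50], "b2": [5, 5, 5]}
    assert ki67_intratumoral_hi(blocks, pool=True).value == pytest.approx(25.0)
    assert ki67_intratumoral_hi(blocks, pool=False).value == pytest.approx(50.0)


def test_oracle_examples():
    assert pair_discordance_oracle(["A", "A", "A"]) == 0.0
    assert pair_discordance_oracle(["A", "B"]) == 1.0
    assert pair_discordance_oracle(["A", "A", "A", "B"]) == 0.5
    with pytest.raises(ValueError):
        pair_discordance_oracle(["A"])


@given(
    counts=st.lists(st.integers(0, 8), min_size=4, max_size=4).filter(
        lambda c: 2 <= sum(c) <= 12
    )
)
@settings(max_examples=300, deadline=None)
def test_hi_equals_oracle_exactly(counts):
    """Closed-form HI equals brute-force pair enumeration in exact rational
    arithmetic, and label naming/permutation does not matter."""
    labels = [lab for lab, c in zip("wxyz", counts) for _ in range(c)]
    named = dict(zip("wxyz", counts))
    res = subtype_hi(named)
    exact = Fraction(res.n_discordant * 100, res.n_pairs)
    n = sum(counts)
    disc = Fraction(
        sum(1 for i in range(n) for j in range(i + 1, n) if labels[i] != labels[j]),
        n * (n - 1) // 2,
    )
    assert exact == 100 * disc
    # category-name permutation invariance
    permuted = dict(zip("zyxw", counts))
    assert subtype_hi(permuted).value == res.value


def test_hi_gini_simpson_limit():
    """For fixed proportions, HI/100 -> 1 - sum(p^2) at rate O(1/n)."""
    p = np.array([0.4, 0.3, 0.2, 0.1])
    gs = 1 - np.sum(p**2)
    for n in (10, 100, 1000, 10000):
        counts = dict(zip("abcd", (p * n).astype(int)))
        hi = subtype_hi(counts).value / 100
        assert abs(hi - gs) <= 1.0 / n + 1e-12


def test_hi_maximal_for_balanced_counts():
    """With four categories and n fixed, HI is maximal when counts are as
    equal as possible, and zero iff one category holds everything."""
    n = 8
    balanced = subtype_hi({"a": 2, "b": 2, "c": 2, "d": 2}).value
    for counts in [(8, 0, 0, 0), (5, 1, 1, 1), (4, 2, 1, 1), (3, 3, 1, 1)]:
        assert subtype_hi(dict(zip("abcd", counts))).value <= balanced
    assert subtype_hi({"a": n}).value == 0.0


def test_dichotomize_hi():
    assert dichotomize_hi(80) == "high"
    assert dichotomize_hi(0) == "low"
    assert dichotomize_hi(50) == "low"     # strict '>' at the cutoff
    assert dichotomize_hi(None) is None


def test_bootstrap_degenerate_input_flagged():
    b = bootstrap_mean_ci([30, 30, 30, 30], seed=1)
    assert (b.point_estimate, b.ci_low, b.ci_high) == (30, 30, 30)
    assert b.degenerate


def test_bootstrap_row_order_invariant_and_deterministic():
    vals = [12.0, 55.0, 3.0, 70.0, 41.0, 29.0]
    a = bootstrap_mean_ci(vals, seed=9)
    b = bootstrap_mean_ci(vals[::-1], seed=9)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
    assert a.ci_low <= a.point_estimate <= a.ci_high


def test_bca_reduces_to_percentile_without_correction():
    lo, hi = _bca_percentiles(z0=0.0, a=0.0, alpha=0.05)
    assert lo == pytest.approx(0.025)
    assert hi == pytest.approx(0.975)


def test_expected_hi_dirichlet_multinomial_closed_form():
    # symmetric alpha=(1,1,1,1): P(same) = 2*4/(4*5) = 0.4 -> HI = 60
    assert expected_hi_dirichlet_multinomial([1, 1, 1, 1]) == pytest.approx(60.0)
    # concentration -> infinity approaches Gini-Simpson of the mean
    big = expected_hi_dirichlet_multinomial(np.array([0.4, 0.3, 0.2, 0.1]) * 1e7)
    assert big == pytest.approx(70.0, abs=0.01)


def test_expected_hi_matches_simulation():
    """Mean HI over many simulated patients matches the DM closed form."""
    rng = np.random.default_rng(2024)
    alpha = np.array([4.0, 1.0, 0.6, 0.4])
    expected = expected_hi_dirichlet_multinomial(alpha)
    his = []
    for _ in range(4000):
        p = rng.dirichlet(alpha)
        counts = rng.multinomial(8, p)
        his.append(subtype_hi(dict(zip("abcd", counts))).value)
    assert np.mean(his) == pytest.approx(expected, abs=1.0)
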