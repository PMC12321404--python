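"""Rank tests, Holm/Bonferroni handling, Hodges-Lehmann shifts, the
random-intercept logistic site model, and duration summaries."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from methet.associations import (
    ClinicalTimeline,
    bonferroni_gate,
    duration_stats,
    kw_test,
    median_diff_ci,
    ne_site_model,
    pairwise_mwu_holm,
)


def test_kw_separated_groups_significant():
    res = kw_test({"a": [1, 2, 3], "b": [101, 102, 103], "c": [201, 202, 203]})
    assert res.p_value < 0.05


def test_kw_requires_two_groups_and_handles_degenerate():
    with pytest.raises(ValueError):
        kw_test({"a": [1, 2, 3]})
    assert kw_test({"a": [5, 5], "b": [5, 5, 5]}).p_value == 1.0


def test_kw_type_one_error_near_nominal():
    """Identical distributions: rejection rate about 5% at alpha=0.05."""
    rng = np.random.default_rng(77)
    rejections = 0
    reps = 400
    for _ in range(reps):
        g = {k: rng.normal(0, 1, 50) for k in "abc"}
        rejections += kw_test(g).p_value < 0.05
    assert 0.02 <= rejections / reps <= 0.08


def test_holm_adjustment_matches_definition():
    rng = np.random.default_rng(3)
    groups = {k: rng.normal(loc, 1, 15) for k, loc in
              zip("abc", (0.0, 0.5, 2.0))}
    results = pairwise_mwu_holm(groups)
    assert len(results) == 3
    raw = [r.p_value for r in results]
    expected = multipletests(raw, method="holm")[1]
    assert [r.p_adjusted for r in results] == pytest.approx(list(expected))
    # step-down multipliers (3, 2, 1) on sorted raw p, with monotonicity
    order = np.argsort(raw)
    manual = np.minimum.accumulate(
        np.minimum((np.array([3, 2, 1]) * np.array(raw)[order])[::-1], 1.0)
    )[::-1]
    assert sorted(r.p_adjusted for r in results) == pytest.approx(sorted(manual))


def test_holm_identical_groups_adjusted_to_one():
    groups = {"a": [1, 2, 3, 4], "b": [1, 2, 3, 4], "c": [1, 2, 3, 4]}
    assert all(r.p_adjusted == 1.0 for r in pairwise_mwu_holm(groups))


def test_rank_tests_invariant_to_monotone_transform():
    rng = np.random.default_rng(8)
    groups = {k: rng.lognormal(m, 0.5, 20) for k, m in zip("ab", (0.0, 0.8))}
    p_raw = kw_test(groups).p_value
    p_log = kw_test({k: np.log(v) for k, v in groups.items()}).p_value
    assert p_raw == pytest.approx(p_log)


def test_hodges_lehmann_pure_shift():
    y = [3.0, 7.0, 1.0, 9.0, 4.0]
    x = [v + 10 for v in y]
    res = median_diff_ci(x, y)
    assert res.estimate == pytest.approx(10.0)


def test_hodges_lehmann_identical_samples():
    x = [1.0, 2.0, 3.0, 4.0]
    res = median_diff_ci(x, x)
    assert res.estimate == pytest.approx(0.0)
    assert res.ci_low <= 0 <= res.ci_high


def test_hodges_lehmann_recovers_simulated_shift():
    rng = np.random.default_rng(11)
    for _ in range(5):
        x = rng.normal(50, 5, 100)
        y = rng.normal(35, 5, 100)
        res = median_diff_ci(x, y)
        assert 13 <= res.estimate <= 17
        assert res.ci_low <= res.estimate <= res.ci_high


@pytest.mark.parametrize(
    "p, significant",
    [(0.002, True), (0.0024, False), (0.04, False), (0.0001, True)],
)
def test_bonferroni_gate_strict_threshold(p, significant):
    assert bonferroni_gate([p], m=21)[0] is significant


def _simulate_clustered(rng, n_pat=50, n_s=10, lor=np.log(4.8), sd=1.0):
    rows = []
    for i in range(n_pat):
        u = rng.normal(0, sd)
        for _ in range(n_s):
            site = "liver" if rng.random() < 0.4 else "bone"
            eta = -1.0 + (lor if site == "liver" else 0.0) + u
            rows.append({
                "patient_id": f"p{i}", "site": site,
                "ne_positive": int(rng.random() < 1 / (1 + np.exp(-eta))),
            })
    return pd.DataFrame(rows)


def test_mixed_logit_reduces_to_logistic_when_sigma_zero():
    df = _simulate_clustered(np.random.default_rng(7), sd=0.0)
    m = ne_site_model(df, fix_sigma=0.0)
    X = np.column_stack([np.ones(len(df)), (df.site == "liver").astype(float)])
    ref = sm.Logit(df.ne_positive, X).fit(disp=0)
    assert m.coef["intercept"] == pytest.approx(ref.params.iloc[0], abs=1e-4)
    assert m.coef["liver"] == pytest.approx(ref.params.iloc[1], abs=1e-4)


def test_mixed_logit_recovers_simulated_odds_ratio():
    """50 patients x 10 samples, true liver-vs-bone OR 4.8, intercept SD 1."""
    ors = []
    for k in range(4):
        df = _simulate_clustered(np.random.default_rng(100 + k))
        m = ne_site_model(df)
        assert m.converged
        ors.append(m.odds_ratios["liver"])
    assert 3.2 <= float(np.median(ors)) <= 7.2


def test_mixed_logit_input_contracts():
    df = pd.DataFrame({
        "patient_id": ["a", "a", "b", "b"],
        "site": ["bone"] * 4,
        "ne_positive": [0, 1, 0, 1],
    })
    with pytest.raises(ValueError):
        ne_site_model(df)  # bone-only input


def test_mixed_logit_flags_constant_outcome_site():
    rng = np.random.default_rng(5)
    df = _simulate_clustered(rng, n_pat=20, n_s=6, sd=0.5)
    extra = pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(10)],
        "site": ["lung"] * 10,
        "ne_positive": [1] * 10,
    })
    m = ne_site_model(pd.concat([df, extra], ignore_index=True))
    assert "lung" in m.non_estimable


def test_clinical_timeline_durations_and_ordering():
    t = ClinicalTimeline("P1", diagnosis_day=0, death_day=730)
    assert t.duration_years("diagnosis_day") == pytest.approx(2.0, abs=0.01)
    with pytest.raises(ValueError):
        ClinicalTimeline("P2", diagnosis_day=100, death_day=50)
    assert ClinicalTimeline("P3").duration_years("diagnosis_day") is None


def test_duration_stats_groups_and_exclusions():
    timelines = [
        ClinicalTimeline("a1", first_bone_met_day=0, death_day=365.25),
        ClinicalTimeline("a2", first_bone_met_day=0, death_day=3 * 365.25),
        ClinicalTimeline("b1", first_bone_met_day=0, death_day=365.25),
        ClinicalTimeline("b2", first_bone_met_day=0, death_day=3 * 365.25),
        ClinicalTimeline("c1", first_bone_met_day=0, death_day=None),  # excluded
    ]
    grouping = {"a1": "g1", "a2": "g1", "b1": "g2", "b2": "g2", "c1": "g1"}
    res = duration_stats(timelines, grouping)
    assert res.per_group["g1"]["median"] == pytest.approx(2.0)
    assert res.per_group["g1"]["median"] == res.per_group["g2"]["median"]
    assert res.n_excluded == 1
    assert res.global_test is not None
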