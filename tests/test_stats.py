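"""Statistical layer: exact/approximate Mann–Whitney, ANOVA identities,
normality and variance checks, BH adjustment, group comparison dispatch."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.stats import rankdata

from patchkit import (
    bh_adjust,
    compare_groups,
    ks_normality,
    levene_test,
    mann_whitney_u,
    one_way_anova,
    significance_stars,
)
from patchkit.stats import StatsPlan

# ---------------------------------------------------------------------------
# independent oracle: brute-force enumeration of the Mann–Whitney null
# ---------------------------------------------------------------------------


def mwu_null_distribution(n: int, m: int) -> np.ndarray:
    """U statistic over every assignment of n ranks among n+m (exact null)."""
    ranks = np.arange(1, n + m + 1)
    return np.array(
        [ranks[list(c)].sum() - n * (n + 1) / 2 for c in combinations(range(n + m), n)]
    )


def enumeration_p(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    n, m = len(x), len(y)
    ranks = rankdata(np.concatenate([x, y]))
    u = ranks[:n].sum() - n * (n + 1) / 2
    null = mwu_null_distribution(n, m)
    lo, hi = min(u, n * m - u), max(u, n * m - u)
    return min(1.0, (np.sum(null <= lo) + np.sum(null >= hi)) / len(null))


def test_worked_mwu_case():
    u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)  # 2/20 assignments as extreme


def test_exact_mwu_matches_enumeration_on_random_samples():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(1, 9))
        m = int(rng.integers(1, 13 - n))
        x, y = rng.normal(size=n), rng.normal(size=m)
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(enumeration_p(x, y), abs=1e-12)


def test_identical_samples_with_ties_give_p_near_one():
    x = [1.0, 1.0, 2.0, 3.0, 3.0, 4.0, 5.0, 5.0, 6.0]
    _, p = mann_whitney_u(x, x)
    assert p > 0.9


def test_exact_and_asymptotic_mwu_agree_for_moderate_n():
    rng = np.random.default_rng(1)
    diffs = []
    for _ in range(50):
        x, y = rng.normal(size=8), rng.normal(size=8)
        pe = sps.mannwhitneyu(x, y, method="exact").pvalue
        pa = sps.mannwhitneyu(x, y, method="asymptotic").pvalue
        diffs.append(abs(pe - pa))
    assert np.median(diffs) < 0.01
    assert max(diffs) < 0.02  # continuity-corrected normal tail


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


def test_anova_closed_form():
    f, p = one_way_anova([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]])
    assert f == pytest.approx(1.5)  # SSB = 1.5, SSW = 4, df 1 and 4
    assert p == pytest.approx(float(sps.f.sf(1.5, 1, 4)))


def test_anova_identical_groups():
    f, p = one_way_anova([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]])
    assert (f, p) == (0.0, 1.0)


def test_anova_equals_t_squared_for_two_groups():
    rng = np.random.default_rng(2)
    x, y = rng.normal(size=12), rng.normal(0.5, 1, 15)
    f, p_f = one_way_anova([x, y])
    t, p_t = sps.ttest_ind(x, y)
    assert f == pytest.approx(t**2, rel=1e-10)
    assert p_f == pytest.approx(p_t, rel=1e-9)


def test_anova_rejects_tiny_groups():
    with pytest.raises(ValueError):
        one_way_anova([[1.0], [2.0, 3.0]])


def test_ks_normality_on_normal_quantiles():
    from scipy.special import ndtri

    x = ndtri((np.arange(1, 101) - 0.5) / 100)
    d, p = ks_normality(x)
    assert d < 0.05
    assert 0.0 <= d <= 1.0


def test_ks_normality_rejects_bimodal():
    x = np.array([0.0] * 50 + [10.0] * 50)
    _, p = ks_normality(x)
    assert p < 0.01


def test_ks_normality_guards():
    with pytest.raises(ValueError):
        ks_normality([1.0, 1.0, 1.0, 1.0, 1.0])  # zero variance
    with pytest.raises(ValueError):
        ks_normality([1.0, 2.0])  # too small


def test_levene_identical_deviation_sets():
    w, p = levene_test([[1.0, 2.0, 3.0], [11.0, 12.0, 13.0]])
    assert w == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_levene_detects_large_variance_ratio():
    rng = np.random.default_rng(3)
    hits = 0
    for _ in range(100):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 4, 30)  # variance ratio 16
        _, p = levene_test([x, y])
        hits += p < 0.05
    assert hits >= 90


def test_bh_adjustment_cases():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
def test_bh_adjustment_is_monotone_and_bounded(pvals):
    adj = bh_adjust(pvals)
    assert np.all(adj <= 1.0 + 1e-12)
    assert np.all(adj >= np.asarray(pvals) - 1e-12)
    order = np.argsort(pvals)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_significance_star_thresholds():
    assert significance_stars(0.2) == ""
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(0.0004) == "***"
    assert significance_stars(0.00004) == "****"


# ---------------------------------------------------------------------------
# compare_groups dispatch
# ---------------------------------------------------------------------------


def _null_table(n=12, seed=0):
    from patchkit import GroupSpec, draw_cohort_features

    return draw_cohort_features(
        [GroupSpec("control", 1, n, line_cv=0.0), GroupSpec("case", 1, n, line_cv=0.0)],
        seed=seed,
    )


def test_identical_groups_give_p_one():
    df = _null_table(n=10, seed=4)
    ctrl = df[df.group_label == "control"].copy()
    dup = ctrl.copy()
    dup["group_label"] = "case"
    dup["cell_id"] = dup["cell_id"] + "_dup"
    res = compare_groups(pd.concat([ctrl, dup], ignore_index=True))
    for r in res:
        assert r.p_value > 0.9
        assert r.direction == "case = control"


def test_sem_definition_matches_sd():
    df = _null_table(n=15, seed=5)
    res = compare_groups(df)
    r = next(r for r in res if r.feature_name == "capacitance_pF")
    vals = df[df.group_label == "control"]["capacitance_pF"].to_numpy()
    assert r.sem_control * np.sqrt(len(vals)) == pytest.approx(np.std(vals, ddof=1))
    assert r.mean_control == pytest.approx(vals.mean())


def test_compare_groups_input_errors():
    df = _null_table()
    with pytest.raises(ValueError, match="control"):
        compare_groups(df, control_label="nope")
    with pytest.raises(ValueError, match="missing"):
        compare_groups(df.drop(columns=["epsc_rate_hz"]))
    only = df[df.group_label == "control"]
    with pytest.raises(ValueError):
        compare_groups(only)


def test_compare_groups_attaches_assumption_checks():
    df = _null_table(n=30, seed=6)
    res = compare_groups(df)
    anova_results = [r for r in res if r.test_name == "anova"]
    assert anova_results
    for r in anova_results:
        assert "levene_p" in r.assumptions
        assert any(k.startswith("ks_normality_p") for k in r.assumptions)


def test_bh_option_populates_adjusted_p():
    df = _null_table(n=10, seed=7)
    res = compare_groups(df, StatsPlan(adjust_bh=True))
    per_step = [r for r in res if r.test_name == "anova" and "band" not in r.feature_name]
    assert per_step and all(r.adjusted_p is not None for r in per_step)
    for r in per_step:
        assert r.adjusted_p >= r.p_value - 1e-12
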