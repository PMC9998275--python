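"""Trend-battery unit tests: RTM algebra, sign/Wilcoxon tests, robust fits."""

import itertools

import numpy as np
import pytest
import scipy.stats as st_scipy
from hypothesis import given, settings, strategies as st

from axialtrends import (
    AncestralEstimateSet,
    branch_pairs,
    ml_ancestral_states,
    robust_regression,
    rtm_adjusted_differences,
    run_trend_battery,
    sign_test,
    wilcoxon_tests,
)
from axialtrends.errors import DegenerateInputError, DomainError
from axialtrends.simulate import SimulationConfig, simulate_dataset

from conftest import random_tree_and_trait


# ----------------------------------------------------------------------
# regression-to-the-mean adjustment
# ----------------------------------------------------------------------
def test_identical_vectors_cancel():
    x = np.array([1.0, 4.0, 2.0, 8.0])
    changes = rtm_adjusted_differences(x, x)
    assert changes.r == pytest.approx(1.0)
    assert np.allclose(changes.d1, 0.0, atol=1e-12)


def test_constant_shift_cancels():
    x = np.array([1.0, 4.0, 2.0, 8.0])
    changes = rtm_adjusted_differences(x, x + 5.0)
    assert np.allclose(changes.d1, 0.0, atol=1e-12)


def test_hand_evaluated_formulas():
    """Direct spreadsheet-style evaluation of the D/D1 expressions."""
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 2.0, 3.0, 8.0])
    r = np.corrcoef(x, y)[0, 1]
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    adj = 2 * r * sx * sy / (sx**2 + sy**2)
    d_expected = -(r * (x - x.mean()) - (y - y.mean()))
    d1_expected = -(adj * (x - x.mean()) - (y - y.mean()))
    got_d = rtm_adjusted_differences(x, y, force_variant="D")
    got_d1 = rtm_adjusted_differences(x, y, force_variant="D1")
    assert np.allclose(got_d.d1, d_expected, atol=1e-12)
    assert np.allclose(got_d1.d1, d1_expected, atol=1e-12)
    assert got_d.r == pytest.approx(r)
    assert got_d1.adj == pytest.approx(adj)
    # gate: variances 1.667 vs 10.9 are not extreme enough for n=4
    gated = rtm_adjusted_differences(x, y)
    assert gated.variant_used in ("D", "D1")
    cdf = st_scipy.f.cdf(sx**2 / sy**2, 3, 3)
    assert gated.variance_test_p == pytest.approx(2 * min(cdf, 1 - cdf))


vectors = st.lists(
    st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=4, max_size=30
)


@settings(max_examples=100, derandomize=True)
@given(vectors, st.floats(min_value=-10, max_value=10), st.integers(0, 2**16))
def test_mean_zero_and_shift_invariance(x, shift, seed):
    x = np.asarray(x)
    rng = np.random.default_rng(seed)
    y = x + rng.normal(0, 1, size=x.size)
    if x.var() == 0 and y.var() == 0:
        return
    changes = rtm_adjusted_differences(x, y)
    assert abs(changes.d1.mean()) < 1e-10
    shifted = rtm_adjusted_differences(x + shift, y - shift)
    assert np.allclose(shifted.d1, changes.d1, atol=1e-8)


def test_degenerate_inputs_rejected():
    with pytest.raises(DegenerateInputError):
        rtm_adjusted_differences([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
    with pytest.raises(DomainError):
        rtm_adjusted_differences([1.0, 2.0], [1.0, 2.0])


# ----------------------------------------------------------------------
# sign test and Wilcoxon tests
# ----------------------------------------------------------------------
def test_sign_test_exact_values():
    assert sign_test([1, 1, 1, 1, -1]) == pytest.approx(0.375)
    assert sign_test([1, -1, 2, -2]) == pytest.approx(1.0)
    assert sign_test([1] * 10) == pytest.approx(2 * 0.5**10)
    # zeros excluded from the count
    assert sign_test([1, 1, 1, 1, -1, 0, 0]) == pytest.approx(0.375)
    with pytest.raises(DegenerateInputError):
        sign_test([0.0, 0.0])


def test_wilcoxon_symmetric_sample():
    one_p, two_p = wilcoxon_tests([-2.0, -1.0, 1.0, 2.0])
    assert one_p == pytest.approx(1.0)
    assert two_p == pytest.approx(1.0)


def test_wilcoxon_one_sample_exact_small_n():
    one_p, two_p = wilcoxon_tests([1.0, 2.0, 3.0, 4.0, 5.0])
    assert one_p == pytest.approx(0.0625)  # 2/32, all ranks positive
    assert two_p is None  # no negative side


def test_wilcoxon_two_sample_matches_enumeration():
    """Exact rank-sum reference by enumerating all 20 assignments of
    ranks to the two samples."""
    pos = [3.0, 4.0, 5.0]
    neg_abs = [1.0, 1.0, 2.0]
    pooled = pos + neg_abs

    def u_stat(sample_a, sample_b):
        return sum(
            (a > b) + 0.5 * (a == b) for a in sample_a for b in sample_b
        )

    observed = u_stat(pos, neg_abs)
    mean_u = len(pos) * len(neg_abs) / 2
    count = total = 0
    for combo in itertools.combinations(range(6), 3):
        a = [pooled[i] for i in combo]
        b = [pooled[i] for i in range(6) if i not in combo]
        total += 1
        if abs(u_stat(a, b) - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
    expected_p = count / total
    d1 = np.array(pos + [-v for v in neg_abs])
    _, two_p = wilcoxon_tests(d1)
    assert two_p == pytest.approx(expected_p, abs=0.02)


# ----------------------------------------------------------------------
# robust regression
# ----------------------------------------------------------------------
def test_exact_line_recovered():
    x = np.arange(10.0)
    res = robust_regression(x, 2 * x + 1)
    assert res.slope == pytest.approx(2.0, abs=1e-8)
    assert res.intercept == pytest.approx(1.0, abs=1e-8)


def test_constant_response_gives_zero_slope():
    res = robust_regression(np.arange(8.0), np.full(8, 3.5))
    assert res.slope == 0.0


def test_resists_gross_outlier():
    rng = np.random.default_rng(11)
    x = np.linspace(0, 10, 40)
    y_clean = 1.5 * x + 2 + rng.normal(0, 0.1, x.size)
    clean_slope = np.polyfit(x, y_clean, 1)[0]
    y = y_clean.copy()
    y[5] += 80.0  # gross outlier
    robust = robust_regression(x, y)
    ols_slope = np.polyfit(x, y, 1)[0]
    assert abs(robust.slope - clean_slope) / clean_slope < 0.05
    assert abs(ols_slope - clean_slope) > abs(robust.slope - clean_slope)


def test_constant_predictor_rejected():
    with pytest.raises(DomainError):
        robust_regression(np.ones(6), np.arange(6.0))


# ----------------------------------------------------------------------
# battery
# ----------------------------------------------------------------------
def _pairs_for(seed, n_tips, **kwargs):
    tree, _, tips = random_tree_and_trait(seed, n_tips, **kwargs)
    est = ml_ancestral_states(tree, tips)
    return branch_pairs(tree, est), est


def test_single_group_equals_pooled():
    pairs, est = _pairs_for(2, 40)
    groups = ["G1"] * len(pairs)
    summaries = run_trend_battery(pairs, est, groups=groups, min_group_branches=5)
    assert len(summaries) == 2
    pooled, only = summaries
    assert pooled.sign_test_p == only.sign_test_p
    assert pooled.wilcoxon_one_sample_p == only.wilcoxon_one_sample_p
    assert pooled.d1_vs_ancestor_slope == only.d1_vs_ancestor_slope


def test_small_groups_skipped():
    pairs, est = _pairs_for(4, 40)
    groups = ["tiny"] * 3 + ["big"] * (len(pairs) - 3)
    summaries = run_trend_battery(pairs, est, groups=groups, min_group_branches=10)
    assert [s.group_label for s in summaries] == ["ALL", "big"]


def test_driven_regime_detected():
    """A drifted history fed to the battery (true branch values) shows a
    significant increase/decrease imbalance and node values that fall
    with node age (younger nodes more complex).  Note the direction of
    the count imbalance: mean-centering makes the adjusted differences
    inherit the right skew of Yule branch lengths under uniform drift,
    so decreases outnumber increases even though the trend is upward —
    the age regression carries the direction."""
    rejections = 0
    for seed in range(20, 30):
        data = simulate_dataset(
            SimulationConfig(n_tips=150, seed=seed), regime="driven"
        )
        truth = AncestralEstimateSet(
            node_values=data.true_node_values,
            node_ages=data.tree.node_ages(),
            sigma2_hat=data.config.sigma2,
            tip_values=data.tip_values,
        )
        pairs = branch_pairs(data.tree, truth)
        (summary,) = run_trend_battery(pairs, truth)
        rejections += summary.sign_test_p < 0.05
        # per replicate: the upward trend is visible against node age
        assert summary.value_vs_age_slope < 0
        assert summary.value_vs_age_slope_p < 0.05
    assert rejections >= 5


def test_counts_partition_branches():
    pairs, est = _pairs_for(6, 60)
    (summary,) = run_trend_battery(pairs, est)
    assert (
        summary.n_increase + summary.n_decrease + summary.n_zero
        == summary.n_branches
        == len(pairs)
    )
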