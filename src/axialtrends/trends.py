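"""Descendant–ancestor trend tests with regression-to-the-mean correction.

Paired ancestor (X) and descendant (Y) values estimated on the same
tree are not independent: because the correlation between them is
imperfect, raw differences Y − X are biased toward the mean (extreme
ancestors appear to "move back"), which can masquerade as or mask a
directional trend.  The correction used here replaces the raw
difference with

    D  = r   * (X − mean(X)) − (Y − mean(Y))        (equal variances)
    D1 = adj * (X − mean(X)) − (Y − mean(Y))        (unequal variances)

with r the Pearson correlation of X and Y and
adj = 2 r sX sY / (varX + varY) a shrinkage coefficient; a two-sided
variance-ratio test decides which coefficient applies.  The sign of
the result is then reversed so that positive entries mean the
descendant exceeds the ancestor after adjustment.  Both formulas have
exactly zero mean by construction, so any asymmetry between positive
and negative entries is directional signal, which the sign test, the
one-sample Wilcoxon signed-rank test and a two-sample Wilcoxon
rank-sum test (positive values vs magnitudes of negative values)
interrogate.  Robust (Huber) regressions relate the adjusted
differences to ancestral values, and node estimates to node ages.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .ancestral import AncestralEstimateSet
from .errors import DegenerateInputError, DomainError

__all__ = [
    "BranchChangeSet",
    "TrendSummary",
    "rtm_adjusted_differences",
    "sign_test",
    "wilcoxon_tests",
    "robust_regression",
    "run_trend_battery",
]


@dataclass
class BranchChangeSet:
    """Paired ancestor/descendant values with adjusted differences."""

    X: np.ndarray  # ancestor values
    Y: np.ndarray  # descendant values
    d1: np.ndarray  # adjusted differences, positive = increase
    variant_used: str  # "D" (r coefficient) or "D1" (adj coefficient)
    r: float
    adj: float
    variance_test_p: float
    meta: pd.DataFrame | None = None


def rtm_adjusted_differences(
    X: Sequence[float],
    Y: Sequence[float],
    alpha: float = 0.05,
    variance_test: str = "f",
    force_variant: str | None = None,
    meta: pd.DataFrame | None = None,
) -> BranchChangeSet:
    """Adjusted descendant−ancestor differences, corrected for
    regression to the mean.

    A two-sided test of var(X) = var(Y) (variance-ratio F by default,
    Levene behind the flag) at ``alpha`` picks the coefficient: the
    Pearson r when equality is not rejected, the shrinkage coefficient
    ``adj`` when it is.  ``force_variant`` ("D" or "D1") bypasses the
    gate.  The returned differences are sign-reversed so positive
    entries mean increase; their mean is zero to machine precision.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise DomainError("X and Y must have equal length")
    n = X.size
    if n < 3:
        raise DomainError("need at least 3 ancestor/descendant pairs")
    var_x = X.var(ddof=1)
    var_y = Y.var(ddof=1)
    if var_x == 0 and var_y == 0:
        raise DegenerateInputError("both X and Y are constant")
    r = float(np.corrcoef(X, Y)[0, 1]) if var_x > 0 and var_y > 0 else 0.0
    adj = float(2.0 * r * np.sqrt(var_x) * np.sqrt(var_y) / (var_x + var_y))

    if variance_test == "f":
        if var_y > 0:
            f_stat = var_x / var_y
            cdf = st.f.cdf(f_stat, n - 1, n - 1)
            var_p = float(2 * min(cdf, 1 - cdf))
        else:
            var_p = 0.0
    elif variance_test == "levene":
        var_p = float(st.levene(X, Y, center="median").pvalue)
    else:
        raise DomainError(f"unknown variance test {variance_test!r}")

    if force_variant is not None:
        variant = force_variant
        if variant not in ("D", "D1"):
            raise DomainError("force_variant must be 'D' or 'D1'")
    else:
        variant = "D1" if var_p < alpha else "D"
    coef = r if variant == "D" else adj
    raw = coef * (X - X.mean()) - (Y - Y.mean())
    d1 = -raw  # reversed: positive = descendant above ancestor
    return BranchChangeSet(
        X=X, Y=Y, d1=d1, variant_used=variant, r=r, adj=adj,
        variance_test_p=var_p, meta=meta,
    )


def sign_test(d1: Sequence[float]) -> float:
    """Exact two-sided binomial test of increases vs decreases.

    Zeros are excluded; the p-value is the two-sided binomial
    probability of the observed split under a 1:1 null.
    """
    d1 = np.asarray(d1, dtype=float)
    n_pos = int((d1 > 0).sum())
    n_neg = int((d1 < 0).sum())
    if n_pos + n_neg == 0:
        raise DegenerateInputError("all differences are zero")
    return float(st.binomtest(n_pos, n_pos + n_neg, 0.5).pvalue)


def wilcoxon_tests(d1: Sequence[float]) -> tuple[float, float | None]:
    """One-sample signed-rank and two-sample rank-sum tests on D1.

    The one-sample test asks whether the adjusted differences are
    symmetric about zero (exact null distribution for small samples
    without ties, normal approximation with continuity correction
    otherwise).  The two-sample test compares the positive values
    against the magnitudes of the negative values; it returns None when
    either side is empty (not applicable rather than an error).
    """
    d1 = np.asarray(d1, dtype=float)
    nonzero = d1[d1 != 0]
    if nonzero.size == 0:
        raise DegenerateInputError("all differences are zero")
    one_sample_p = float(
        st.wilcoxon(nonzero, alternative="two-sided", correction=True, method="auto").pvalue
    )
    pos = nonzero[nonzero > 0]
    neg_abs = -nonzero[nonzero < 0]
    if pos.size == 0 or neg_abs.size == 0:
        return one_sample_p, None
    if pos.size + neg_abs.size <= 25:
        method = st.PermutationMethod(n_resamples=200_000, random_state=0)
    else:
        method = "asymptotic"
    two_sample_p = float(
        st.mannwhitneyu(pos, neg_abs, alternative="two-sided", method=method).pvalue
    )
    return one_sample_p, two_sample_p


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_p: float
    intercept_p: float
    weights: np.ndarray
    n: int


def robust_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Huber M-estimate of a straight line with heteroskedasticity-robust
    Wald tests.

    Iteratively reweighted least squares with the canonical Huber
    tuning constant 1.345 and MAD residual scale (coefficient tolerance
    1e-8, at most 200 iterations).  Coefficient p-values come from Wald
    F-tests using an HC3-type sandwich covariance evaluated on the
    final weighted fit, so they remain valid under the heteroskedastic
    residual spread these indices typically show.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise DomainError("robust regression needs at least 4 points")
    if x.var() == 0:
        raise DomainError("constant predictor")
    design = sm.add_constant(x)
    if y.var() == 0:  # exact fit: flat line, no sampling variability
        return RegressionResult(0.0, float(y[0]), 1.0, 0.0, np.ones(n), n)
    model = sm.RLM(y, design, M=sm.robust.norms.HuberT(t=1.345))
    res = model.fit(maxiter=200, tol=1e-8, conv="coefs", scale_est="mad")
    history = res.fit_history["params"]
    if len(history) >= 200:
        delta = np.max(np.abs(np.asarray(history[-1]) - np.asarray(history[-2])))
        if delta > 1e-8:
            raise DomainError(
                f"robust regression did not converge in 200 iterations "
                f"(last coefficient change {delta:.3e})"
            )
    w = np.asarray(res.weights, dtype=float)
    beta = np.asarray(res.params, dtype=float)
    resid = y - design @ beta
    xtwx_inv = np.linalg.inv(design.T @ (w[:, None] * design))
    h = np.einsum("ij,jk,ik->i", design, xtwx_inv, design) * w  # weighted leverage
    h = np.clip(h, 0.0, 1.0 - 1e-10)
    omega = w**2 * resid**2 / (1.0 - h) ** 2  # HC3-type
    cov = xtwx_inv @ (design.T @ (omega[:, None] * design)) @ xtwx_inv
    se = np.sqrt(np.diag(cov))
    f_stats = (beta / se) ** 2
    p = st.f.sf(f_stats, 1, n - 2)
    return RegressionResult(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        slope_p=float(p[1]),
        intercept_p=float(p[0]),
        weights=w,
        n=n,
    )


@dataclass
class TrendSummary:
    """One group's (or the whole tree's) trend-test battery results."""

    group_label: str
    n_branches: int
    n_increase: int
    n_decrease: int
    n_zero: int
    variant_used: str
    r: float
    adj: float
    variance_test_p: float
    sign_test_p: float
    wilcoxon_one_sample_p: float
    wilcoxon_two_sample_p: float | None
    d1_vs_ancestor_slope: float | None = None
    d1_vs_ancestor_slope_p: float | None = None
    d1_vs_ancestor_intercept: float | None = None
    d1_vs_ancestor_intercept_p: float | None = None
    value_vs_age_slope: float | None = None
    value_vs_age_slope_p: float | None = None
    value_vs_age_intercept: float | None = None
    value_vs_age_intercept_p: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _battery_for_subset(
    label: str,
    pairs: pd.DataFrame,
    estimates: AncestralEstimateSet | None,
    alpha: float,
    variance_test: str,
    force_variant: str | None,
) -> TrendSummary:
    changes = rtm_adjusted_differences(
        pairs["ancestor_value"].to_numpy(),
        pairs["descendant_value"].to_numpy(),
        alpha=alpha,
        variance_test=variance_test,
        force_variant=force_variant,
        meta=pairs,
    )
    d1 = changes.d1
    one_p, two_p = wilcoxon_tests(d1)
    summary = TrendSummary(
        group_label=label,
        n_branches=int(d1.size),
        n_increase=int((d1 > 0).sum()),
        n_decrease=int((d1 < 0).sum()),
        n_zero=int((d1 == 0).sum()),
        variant_used=changes.variant_used,
        r=changes.r,
        adj=changes.adj,
        variance_test_p=changes.variance_test_p,
        sign_test_p=sign_test(d1),
        wilcoxon_one_sample_p=one_p,
        wilcoxon_two_sample_p=two_p,
    )
    try:
        reg = robust_regression(changes.X, d1)
        summary.d1_vs_ancestor_slope = reg.slope
        summary.d1_vs_ancestor_slope_p = reg.slope_p
        summary.d1_vs_ancestor_intercept = reg.intercept
        summary.d1_vs_ancestor_intercept_p = reg.intercept_p
    except DomainError:
        pass
    if estimates is not None:
        node_ids = sorted(
            set(pairs["ancestor_id"]) | set(pairs["descendant_id"]),
            key=str,
        )
        values, ages = [], []
        for nid in node_ids:
            try:
                values.append(estimates.value_of(nid))
            except KeyError:
                continue
            ages.append(estimates.node_ages[nid])
        try:
            reg = robust_regression(np.asarray(ages), np.asarray(values))
            summary.value_vs_age_slope = reg.slope
            summary.value_vs_age_slope_p = reg.slope_p
            summary.value_vs_age_intercept = reg.intercept
            summary.value_vs_age_intercept_p = reg.intercept_p
        except DomainError:
            pass
    return summary


def run_trend_battery(
    pairs: pd.DataFrame,
    estimates: AncestralEstimateSet | None = None,
    groups: pd.Series | None = None,
    alpha: float = 0.05,
    min_group_branches: int = 10,
    variance_test: str = "f",
    force_variant: str | None = None,
) -> list[TrendSummary]:
    """Run the full trend battery for the whole tree and per group.

    ``pairs`` is a branch table from :func:`axialtrends.ancestral.branch_pairs`;
    ``groups`` (aligned with its rows) restricts per-group reruns to
    groups contributing at least ``min_group_branches`` branches —
    smaller groups are skipped silently, matching how unstable tiny
    samples would be under these tests.  The first summary is always
    the pooled one, labelled "ALL".
    """
    summaries = [
        _battery_for_subset("ALL", pairs, estimates, alpha, variance_test, force_variant)
    ]
    if groups is not None:
        groups = pd.Series(list(groups), index=pairs.index)
        for label in sorted(groups.dropna().unique(), key=str):
            subset = pairs[groups == label]
            if len(subset) < min_group_branches:
                continue
            try:
                summaries.append(
                    _battery_for_subset(
                        str(label), subset, estimates, alpha, variance_test, force_variant
                    )
                )
            except DegenerateInputError:
                continue
    return summaries
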