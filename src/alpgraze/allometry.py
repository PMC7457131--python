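"""Standardized major axis (SMA) line fitting and multi-group comparison.

SMA fits a line to a bivariate sample by minimising residuals in both
variables, appropriate when neither variable is a predictor of the other
and both carry error — the usual situation for allometric trait pairs.
The slope is b = sign(r) · s_y / s_x, the intercept a = ȳ − b x̄.

For several groups (here: cattle breeds) the fitted lines are compared in
three ways:

* **slope** — a likelihood-ratio test of a common slope.  At slope b the
  residual axis u = y − bx and the fitted axis v = y + bx are uncorrelated
  exactly when b is the group's own SMA slope; the statistic
  LR(b) = −Σ_i n_i log(1 − r²_{uv,i}(b)), minimised over b, is the common
  slope fit, and the minimised LR is χ²_{g−1} under the null.
* **shift** — with a common slope accepted, groups may still sit at
  different places *along* the axis: a Wald χ² test on group means of the
  fitted-axis scores v = y + b_c x.
* **elevation** — or the lines may be offset *in parallel*: a Wald χ² test
  on group intercepts a_i = ȳ_i − b_c x̄_i, with the common-slope sampling
  variance propagated into (and correlated across) the group intercepts.

Also here: Tukey–Kramer range tests for plain group-mean comparisons and a
sequential two-factor ANOVA (breed x paddock size).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .records import DegenerateDataError


@dataclass
class SmaFit:
    group: str
    n: int
    slope: float
    intercept: float
    r: float
    r_squared: float
    slope_ci: tuple[float, float]
    slope_undefined: bool = False  # r exactly 0: slope sign not identifiable


def _moments(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """(x̄, ȳ, s_xx, s_yy, s_xy) with n−1 denominators."""
    return (
        float(x.mean()), float(y.mean()),
        float(x.var(ddof=1)), float(y.var(ddof=1)),
        float(np.cov(x, y, ddof=1)[0, 1]),
    )


def sma_fit(x, y, group: str = "", alpha: float = 0.05) -> SmaFit:
    """Fit a standardized major axis to one bivariate sample.

    The slope confidence interval is the standard F-based one:
    with B = F_{1−α}(1, n−2) · (1 − r²)/(n − 2), the CI is
    b·(√(B+1) ± √B).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise DegenerateDataError(f"need n >= 3 paired observations, got {n}")
    xbar, ybar, sxx, syy, sxy = _moments(x, y)
    if sxx <= 0 or syy <= 0:
        raise DegenerateDataError("zero variance in x or y")
    r = sxy / np.sqrt(sxx * syy)
    undefined = r == 0.0
    sign = 1.0 if r >= 0 else -1.0
    b = sign * np.sqrt(syy / sxx)
    a = ybar - b * xbar
    B = stats.f.ppf(1 - alpha, 1, n - 2) * (1 - r**2) / (n - 2)
    ci = (b * (np.sqrt(B + 1) - np.sqrt(B)), b * (np.sqrt(B + 1) + np.sqrt(B)))
    return SmaFit(
        group=group, n=n, slope=float(b), intercept=float(a),
        r=float(r), r_squared=float(r**2),
        slope_ci=(float(min(ci)), float(max(ci))),
        slope_undefined=bool(undefined),
    )


# ---------------------------------------------------------------------------
# multi-group machinery


def _group_arrays(groups: dict) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for label, (x, y) in groups.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 3:
            raise DegenerateDataError(f"group {label!r}: need n >= 3")
        if x.var() <= 0 or y.var() <= 0:
            raise DegenerateDataError(f"group {label!r}: zero variance")
        out[str(label)] = (x, y)
    return out


def _lr_profile(groups: dict[str, tuple[np.ndarray, np.ndarray]]):
    """LR(b) = −Σ (n_i − 3) log(1 − r²_{uv,i}(b)) as a callable of the slope.

    The n−3 weight is the Fisher-z effective sample size for a correlation
    test and keeps the χ² reference honest at field-scale group sizes.
    """
    moms = []
    for x, y in groups.values():
        _, _, sxx, syy, sxy = _moments(x, y)
        moms.append((x.size, sxx, syy, sxy))

    def lr(b: float) -> float:
        total = 0.0
        for n, sxx, syy, sxy in moms:
            var_u = syy - 2 * b * sxy + b * b * sxx
            var_v = syy + 2 * b * sxy + b * b * sxx
            cov_uv = syy - b * b * sxx
            r2 = cov_uv**2 / (var_u * var_v)
            total += -(n - 3) * np.log(max(1.0 - r2, 1e-300))
        return total

    return lr


@dataclass
class CommonSlopeTest:
    b_common: float
    lr_statistic: float
    df: int
    p_value: float
    var_b: float  # sampling variance of the common slope (profile curvature)


def sma_common_slope(groups: dict) -> CommonSlopeTest:
    """Common SMA slope across groups with the likelihood-ratio test.

    The common slope minimises LR(b); the minimised statistic is χ²_{g−1}
    under equal slopes.  Its sampling variance comes from the curvature of
    the profile (2 / LR'' at the minimum) and feeds the shift/elevation
    Wald tests.
    """
    garr = _group_arrays(groups)
    g = len(garr)
    if g < 2:
        raise DegenerateDataError("need >= 2 groups")
    lr = _lr_profile(garr)
    slopes = [sma_fit(x, y).slope for x, y in garr.values()]
    if len({np.sign(s) for s in slopes}) > 1:
        # groups disagree on slope sign; bracket widely in log-|b| on both signs
        candidates = [abs(s) for s in slopes]
    else:
        candidates = [abs(s) for s in slopes]
    lo = min(candidates) / 10.0
    hi = max(candidates) * 10.0
    sign = np.sign(slopes[0]) or 1.0
    res = optimize.minimize_scalar(
        lambda t: lr(sign * np.exp(t)),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-12},
    )
    b_c = float(sign * np.exp(res.x))
    stat = float(lr(b_c))
    # numerical curvature of the profile in b
    h = max(abs(b_c), 1e-6) * 1e-4
    curv = (lr(b_c + h) - 2 * stat + lr(b_c - h)) / h**2
    if np.isfinite(curv) and curv > 0:
        var_b = 2.0 / curv
    else:
        # numerically flat profile: slope barely identified; a huge but
        # finite variance keeps the downstream Wald tests well defined
        var_b = 1e12 * max(b_c**2, 1.0)
    return CommonSlopeTest(
        b_common=b_c,
        lr_statistic=stat,
        df=g - 1,
        p_value=float(stats.chi2.sf(stat, g - 1)),
        var_b=float(var_b),
    )


@dataclass
class WaldTest:
    statistic: float
    df: int
    p_value: float


def _axis_wald(
    garr: dict[str, tuple[np.ndarray, np.ndarray]],
    b_c: float,
    var_b: float,
    axis: str,
) -> WaldTest:
    """Wald χ² for equality of group means of the residual axis
    (y − b_c x, "elevation") or the fitted axis (y + b_c x, "shift").

    Group score variances use n−2 denominators (slope and intercept
    estimated); the shared common-slope uncertainty enters through the
    score-mean derivative ∓x̄_i, correlating the group means.
    """
    sgn = -1.0 if axis == "residual" else 1.0
    labels = list(garr)
    g = len(labels)
    means = np.empty(g)
    var_means = np.empty(g)
    xbars = np.empty(g)
    ns = np.empty(g)
    for i, lab in enumerate(labels):
        x, y = garr[lab]
        score = y + sgn * b_c * x
        n = x.size
        means[i] = score.mean()
        resid_var = float(score.var(ddof=1)) * (n - 1) / (n - 2)
        var_means[i] = resid_var / n
        xbars[i] = x.mean()
        ns[i] = n
    # d(mean_i)/d(b_c) = sgn * xbar_i -> shared-slope covariance term
    V = np.diag(var_means) + var_b * np.outer(sgn * xbars, sgn * xbars)
    L = np.zeros((g - 1, g))
    L[:, 0] = 1.0
    L[np.arange(g - 1), np.arange(1, g)] = -1.0
    d = L @ means
    W = float(d @ np.linalg.solve(L @ V @ L.T, d))
    # Estimated score variances: use the Hotelling-T² reference with the
    # pooled residual df m = Σ(n_i − 2) instead of the asymptotic χ²:
    # W·(m−p+1)/(p·m) ~ F(p, m−p+1) with p = g−1 contrasts.
    m = float(ns.sum() - 2 * g)
    p_dim = g - 1
    f_stat = W * (m - p_dim + 1) / (p_dim * m)
    p = float(stats.f.sf(f_stat, p_dim, m - p_dim + 1))
    return WaldTest(statistic=W, df=g - 1, p_value=p)


def sma_shift_test(groups: dict, common: CommonSlopeTest) -> WaldTest:
    """Do groups sit at different positions *along* the common axis?"""
    return _axis_wald(_group_arrays(groups), common.b_common, common.var_b, "fitted")


def sma_elevation_test(groups: dict, common: CommonSlopeTest) -> WaldTest:
    """Are the group lines offset *in parallel* (different intercepts)?"""
    return _axis_wald(_group_arrays(groups), common.b_common, common.var_b, "residual")


@dataclass
class GroupedAllometry:
    fits: dict[str, SmaFit]
    common: CommonSlopeTest
    shift: WaldTest
    elevation: WaldTest
    common_slope_rejected: bool  # shift/elevation then use a *forced* common slope
    alpha: float


def grouped_allometry(groups: dict, alpha: float = 0.05) -> GroupedAllometry:
    """Per-group SMA fits plus slope/shift/elevation comparisons.

    If the common-slope test rejects at ``alpha``, the shift and elevation
    tests are still computed from the forced common slope and flagged via
    ``common_slope_rejected`` — the caller decides how to present them.
    """
    garr = _group_arrays(groups)
    fits = {lab: sma_fit(x, y, group=lab) for lab, (x, y) in garr.items()}
    common = sma_common_slope(groups)
    return GroupedAllometry(
        fits=fits,
        common=common,
        shift=sma_shift_test(groups, common),
        elevation=sma_elevation_test(groups, common),
        common_slope_rejected=common.p_value < alpha,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# plain group-mean comparisons


def tukey_pairwise(groups: dict) -> pd.DataFrame:
    """Tukey–Kramer range test on group means (one-way layout).

    Returns a tidy frame (group_a, group_b, mean_diff, q, p_adj) with
    p-values from the studentized range distribution; for two groups this
    reduces to the pooled two-sample t-test.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[lab], dtype=float) for lab in labels]
    if len(labels) < 2:
        raise DegenerateDataError("need >= 2 groups")
    for lab, a in zip(labels, arrays):
        if a.size < 2:
            raise DegenerateDataError(f"group {lab!r}: need n >= 2")
    k = len(labels)
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    df = int(ns.sum() - k)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df
    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": float(diff),
                "q": float(q),
                "p_adj": min(p, 1.0),
            }
        )
    return pd.DataFrame(rows)


def anova_breed_size(
    data: pd.DataFrame,
    response: str,
    breed_col: str = "breed",
    size_col: str = "paddock_size_ha",
) -> pd.DataFrame:
    """Sequential (type-I) ANOVA of response ~ breed + size + breed:size.

    ``size`` is treated as a continuous covariate.  Returns the ANOVA
    table (sum_sq, df, F, PR(>F)) indexed by term.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    if data[breed_col].nunique() < 2:
        raise DegenerateDataError("need >= 2 breeds")
    if data[size_col].nunique() < 2:
        raise DegenerateDataError("paddock size does not vary")
    d = data.rename(columns={response: "_y", breed_col: "_breed", size_col: "_size"})
    model = smf.ols("_y ~ C(_breed) * _size", data=d).fit()
    table = anova_lm(model, typ=1)
    table.index = [
        i.replace("C(_breed)", "breed").replace("_size", "size") for i in table.index
    ]
    return table
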