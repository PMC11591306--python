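"""Group-level statistics for the circle-drawing outcomes.

The battery mirrors the study's analysis plan: one-sided Wilcoxon
signed-rank tests (fraction learned vs zero per group; paired
after-failure vs after-success variability), one-sided Mann-Whitney U
tests (children vs adults), OLS regression of learning on age with
adults capped at 18, a two-sided Pearson chi-square on motivation-score
levels, questionnaire scoring (Cronbach's alpha, item-item correlations,
best-pair mean), and a Gaussian-kernel moving average over log age used
for developmental curves.

The rank tests are implemented as normal approximations with tie and
continuity corrections — the approximation regime for the study's group
sizes (n of roughly 30-70) — and report the z statistic alongside the
p-value, matching how results are conventionally stated.  Exact
enumeration equivalents exist in the test suite as oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupResult",
    "RegressionResult",
    "SmoothedCurve",
    "wilcoxon_signed_rank_one_sided",
    "paired_wilcoxon",
    "mann_whitney_u_one_sided",
    "regress_learning_on_age",
    "chi_square_motivation",
    "cronbach_alpha",
    "motivation_score",
    "smooth_vs_age",
    "group_statistics",
]

#: Default kernel SD for smoothing over log age.
LOG_AGE_BANDWIDTH = math.log(1.1)

#: Age at which adults are grouped for the age regression.
ADULT_AGE_CAP = 18


class UndefinedTestError(ValueError):
    """The test statistic is undefined for this input (e.g. all zeros)."""


@dataclass(frozen=True)
class GroupResult:
    """Outcome of one hypothesis test."""

    statistic_name: str
    z_or_stat: float
    p: float
    n: int
    direction: str  # "one-sided" | "two-sided"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of an outcome on (capped) age."""

    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int


@dataclass(frozen=True)
class SmoothedCurve:
    """Gaussian-weighted moving average over log age."""

    grid: np.ndarray  # log-age grid points
    value: np.ndarray  # weighted mean at each grid point
    bandwidth: float


def _signed_rank_z(diffs: np.ndarray, alternative: str) -> tuple[float, float, int]:
    """z and one/two-sided p for the Wilcoxon signed-rank statistic.

    Exact zeros are dropped before ranking (standard convention); ties in
    |d| get average ranks with the matching variance reduction; a 0.5
    continuity correction is applied toward the null.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise UndefinedTestError("all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: subtract sum(t^3 - t)/48 over tied groups of |d|
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= float(((counts**3 - counts).sum())) / 48.0
    if var <= 0:
        raise UndefinedTestError("zero variance after tie correction")
    sd = math.sqrt(var)
    if alternative == "greater":
        z = (w_plus - mu - 0.5) / sd
        p = float(sps.norm.sf(z))
    elif alternative == "less":
        z = (w_plus - mu + 0.5) / sd
        p = float(sps.norm.cdf(z))
    elif alternative == "two-sided":
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sd
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return z, min(p, 1.0), n


def wilcoxon_signed_rank_one_sided(
    values: Sequence[float],
    null: float = 0.0,
    alternative: str = "greater",
) -> GroupResult:
    """One-sample Wilcoxon signed-rank test against a null location.

    Tests whether the values' location differs from ``null`` in the
    direction of ``alternative`` (default: greater).
    """
    d = np.asarray(values, dtype=float) - null
    z, p, n = _signed_rank_z(d, alternative)
    return GroupResult("wilcoxon_signed_rank", z, p, n, "one-sided")


def paired_wilcoxon(
    after_fail: Sequence[float],
    after_success: Sequence[float],
    alternative: str = "greater",
) -> GroupResult:
    """Paired Wilcoxon signed-rank test on (after_fail - after_success).

    The default alternative "greater" tests whether variability after
    failure exceeds variability after success.
    """
    a = np.asarray(after_fail, dtype=float)
    b = np.asarray(after_success, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    z, p, n = _signed_rank_z(a - b, alternative)
    return GroupResult("paired_wilcoxon", z, p, n, "one-sided")


def mann_whitney_u_one_sided(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "greater",
) -> GroupResult:
    """Mann-Whitney U test (normal approximation, tie-corrected).

    ``alternative="greater"`` tests whether ``group_a`` is stochastically
    larger than ``group_b``.  The reported statistic is the z score; the
    U statistic of group_a is recoverable as ``u_statistic`` on the
    enumeration oracle side.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    u_a = float(ranks[:n1].sum()) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        raise UndefinedTestError("zero variance (all observations tied)")
    sd = math.sqrt(var)
    if alternative == "greater":
        z = (u_a - mu - 0.5) / sd
        p = float(sps.norm.sf(z))
    elif alternative == "less":
        z = (u_a - mu + 0.5) / sd
        p = float(sps.norm.cdf(z))
    elif alternative == "two-sided":
        z = (u_a - mu - 0.5 * np.sign(u_a - mu)) / sd
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    direction = "two-sided" if alternative == "two-sided" else "one-sided"
    return GroupResult("mann_whitney_u", z, min(p, 1.0), n, direction)


def u_statistic(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Mann-Whitney U of group_a: pairs where a > b, ties counting half."""
    a = np.asarray(group_a, dtype=float)[:, None]
    b = np.asarray(group_b, dtype=float)[None, :]
    return float((a > b).sum() + 0.5 * (a == b).sum())


def regress_learning_on_age(
    ages: Sequence[float],
    values: Sequence[float],
    adult_cap: int = ADULT_AGE_CAP,
) -> RegressionResult:
    """OLS of an outcome on age with all adults grouped at ``adult_cap``.

    Ages above the cap contribute the identical predictor value, so the
    fit measures development from childhood to adulthood only.
    """
    x = np.minimum(np.asarray(ages, dtype=float), float(adult_cap))
    y = np.asarray(values, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0.0:
        raise ValueError("capped age is constant; slope undefined")
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n=len(x),
    )


def chi_square_motivation(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> GroupResult:
    """Two-sided Pearson chi-square comparing score distributions.

    Scores are binned at the distinct levels observed across both groups
    (two-item mean scores can take half-point levels), giving a
    2 x levels contingency table with levels - 1 degrees of freedom.
    """
    a = np.round(np.asarray(scores_a, dtype=float), 6)
    b = np.round(np.asarray(scores_b, dtype=float), 6)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    levels = np.unique(np.concatenate([a, b]))
    table = np.array(
        [[(g == lv).sum() for lv in levels] for g in (a, b)], dtype=float
    )
    if table.shape[1] < 2:
        raise UndefinedTestError("only one score level observed")
    chi2, p, _dof, _ = sps.chi2_contingency(table, correction=False)
    return GroupResult("chi_square", float(chi2), float(p), len(a) + len(b), "two-sided")


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha of an (n_respondents, k_items) response matrix.

    ``alpha = k/(k-1) * (1 - sum(var_item) / var_total)`` with sample
    variances; total score is the per-respondent item sum.
    """
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 respondents and >= 2 items")
    k = x.shape[1]
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise UndefinedTestError("zero total-score variance")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


@dataclass(frozen=True)
class MotivationScoring:
    """Questionnaire scoring: per-respondent mean of the best item pair."""

    scores: np.ndarray  # per-respondent mean of the selected pair
    alpha_all: float  # Cronbach's alpha of the full item set
    alpha_pair: float  # alpha of the selected pair
    correlations: np.ndarray  # k x k Pearson item-item correlations
    selected_pair: tuple[int, int]  # column indices of the best pair


def motivation_score(items: np.ndarray) -> MotivationScoring:
    """Score a Likert questionnaire (responses 1-5, complete cases).

    Computes Cronbach's alpha and the Pearson item-item correlation
    matrix, selects the pair of items with the strongest correlation, and
    scores each respondent as the mean of that pair.
    """
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 respondents and >= 2 items")
    corr = np.corrcoef(x, rowvar=False)
    k = corr.shape[0]
    best, best_r = (0, 1), -np.inf
    for i in range(k):
        for j in range(i + 1, k):
            if corr[i, j] > best_r:
                best, best_r = (i, j), corr[i, j]
    pair = x[:, list(best)]
    return MotivationScoring(
        scores=pair.mean(axis=1),
        alpha_all=cronbach_alpha(x),
        alpha_pair=cronbach_alpha(pair),
        correlations=corr,
        selected_pair=best,
    )


def smooth_vs_age(
    ages: Sequence[float],
    values: Sequence[float],
    bandwidth: float = LOG_AGE_BANDWIDTH,
    grid: Optional[Sequence[float]] = None,
) -> SmoothedCurve:
    """Gaussian-weighted moving average of an outcome over log age.

    At each grid point g (log age), the curve value is the weighted mean
    of the observations with weights
    ``exp(-(log(age_i) - g)^2 / (2 * bandwidth^2))``, normalized per grid
    point.  Default grid: each log-transformed integer year from the
    youngest to the oldest observed age.
    """
    a = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(a) != len(y) or len(a) < 2:
        raise ValueError("need >= 2 paired observations")
    if np.any(a <= 0):
        raise ValueError("ages must be positive")
    log_a = np.log(a)
    if grid is None:
        grid_arr = np.log(np.arange(math.floor(a.min()), math.floor(a.max()) + 1))
    else:
        grid_arr = np.asarray(grid, dtype=float)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    w = np.exp(-((log_a[None, :] - grid_arr[:, None]) ** 2) / (2.0 * bandwidth**2))
    value = (w * y[None, :]).sum(axis=1) / w.sum(axis=1)
    return SmoothedCurve(grid=grid_arr, value=value, bandwidth=float(bandwidth))


def _median_iqr(x: np.ndarray) -> dict:
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    return {"median": float(q2), "iqr": [float(q1), float(q3)]}


def group_statistics(summaries) -> dict:
    """Full group-level results from a participant-summary table.

    ``summaries`` is a DataFrame with the participant-summary columns
    (see the io module).  Excluded participants are dropped.  Returns a
    JSON-serializable dict with, per group, median/IQR of the outcome
    measures, the one-sided signed-rank test of fraction learned vs
    zero, and the paired after-failure vs after-success test; plus the
    child-adult Mann-Whitney comparisons and the age regression when
    both groups are present.
    """
    df = summaries[~summaries["excluded"].astype(bool)]
    out: dict = {"n_included": int(len(df)), "groups": {}}
    for name, grp in df.groupby("group"):
        fl = grp["fraction_learned"].to_numpy(dtype=float)
        fail = grp["median_ratio_after_no_reward"].to_numpy(dtype=float)
        succ = grp["median_ratio_after_reward"].to_numpy(dtype=float)
        ok = ~(np.isnan(fail) | np.isnan(succ))
        entry = {
            "n": int(len(grp)),
            "fraction_learned": _median_iqr(fl),
            "ratio_after_no_reward": _median_iqr(fail[~np.isnan(fail)]),
            "ratio_after_reward": _median_iqr(succ[~np.isnan(succ)]),
            "success_frequency": _median_iqr(
                grp["success_frequency"].to_numpy(dtype=float)
            ),
        }
        try:
            r = wilcoxon_signed_rank_one_sided(fl, 0.0, "greater")
            entry["learning_test"] = {"z": r.z_or_stat, "p": r.p, "n": r.n}
        except (UndefinedTestError, ValueError):
            entry["learning_test"] = None
        try:
            r = paired_wilcoxon(fail[ok], succ[ok], "greater")
            entry["variability_test"] = {"z": r.z_or_stat, "p": r.p, "n": r.n}
        except (UndefinedTestError, ValueError):
            entry["variability_test"] = None
        out["groups"][str(name)] = entry

    out["success_frequency"] = _median_iqr(
        df["success_frequency"].to_numpy(dtype=float)
    )
    child = df[df["group"] == "child"]
    adult = df[df["group"] == "adult"]
    if len(child) and len(adult):
        r = mann_whitney_u_one_sided(
            child["fraction_learned"], adult["fraction_learned"], "less"
        )
        out["learning_child_vs_adult"] = {"z": r.z_or_stat, "p": r.p}
        for col, key in [
            ("median_ratio_after_no_reward", "variability_fail_child_vs_adult"),
            ("median_ratio_after_reward", "variability_success_child_vs_adult"),
        ]:
            c = child[col].to_numpy(dtype=float)
            a = adult[col].to_numpy(dtype=float)
            r = mann_whitney_u_one_sided(c[~np.isnan(c)], a[~np.isnan(a)], "greater")
            out[key] = {"z": r.z_or_stat, "p": r.p}
        try:
            reg = regress_learning_on_age(df["age"], df["fraction_learned"])
            out["learning_vs_age"] = {
                "slope": reg.slope,
                "r_squared": reg.r_squared,
                "p": reg.p,
            }
        except ValueError:
            out["learning_vs_age"] = None
    return out
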