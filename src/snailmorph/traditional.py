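"""Traditional morphometrics: aperture ellipse area, relative aperture,
rank correlations, group tests, the determinate-growth comparison, and the
collinearity screen for environmental predictors."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TestResult:
    """A single test statistic with its p-value."""

    name: str
    statistic: float
    p_value: float
    df: float | tuple | None = None
    n: int | None = None
    extra: dict | None = None


def aperture_area(aperture_height: float, aperture_width: float) -> float:
    """Aperture size approximated as an ellipse with the height and width as
    full axes: area = pi * h * w / 4."""
    h = np.asarray(aperture_height, float)
    w = np.asarray(aperture_width, float)
    if np.any(h <= 0) or np.any(w <= 0):
        raise ValueError("aperture axes must be positive")
    return math.pi * h * w / 4 if np.isscalar(aperture_height) else np.pi * h * w / 4


def relative_aperture(shell_height, aperture_height, aperture_width,
                      normalization: str = "height_squared"):
    """Aperture area relative to shell height.

    ``height_squared`` (default) divides by shell_height**2 so the ratio is
    dimensionless and invariant to uniform scaling; ``height`` divides by
    shell_height (area/length, as a literal reading of "relative to shell
    height").  Rankings by the two agree whenever height is constant.
    """
    h = np.asarray(shell_height, float)
    if np.any(h <= 0):
        raise ValueError("shell height must be positive")
    area = aperture_area(aperture_height, aperture_width)
    if normalization == "height_squared":
        return area / h**2
    if normalization == "height":
        return area / h
    raise ValueError(f"unknown normalization {normalization!r}")


def rank_correlation(x, y, method: str = "spearman") -> TestResult:
    """Spearman's rs or Kendall's tau-b (tie-corrected) with large-sample p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "spearman":
        r = stats.spearmanr(x, y)
        return TestResult("spearman_rs", float(r.statistic), float(r.pvalue), n=len(x))
    if method == "kendall":
        r = stats.kendalltau(x, y)
        tau = float(r.statistic)
        # normal-approximation z as printed alongside tau in field software
        n = len(x)
        z = 3 * tau * math.sqrt(n * (n - 1)) / math.sqrt(2 * (2 * n + 5))
        return TestResult("kendall_tau", tau, float(r.pvalue), n=n, extra={"z": z})
    raise ValueError(f"unknown method {method!r}")


def t_test(a, b, paired: bool = False) -> TestResult:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if paired:
        if len(a) != len(b) or len(a) < 2:
            raise ValueError("paired t test needs equal-length samples, n >= 2")
        if np.allclose(a, b):
            return TestResult("t_paired", 0.0, 1.0, df=len(a) - 1, n=len(a))
        r = stats.ttest_rel(a, b)
        return TestResult("t_paired", float(r.statistic), float(r.pvalue),
                          df=float(r.df), n=len(a))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t test needs n >= 2 per group")
    r = stats.ttest_ind(a, b)
    return TestResult("t", float(r.statistic), float(r.pvalue),
                      df=float(r.df), n=len(a) + len(b))


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U with tie-corrected normal approximation.

    U is reported under the smaller-statistic convention; z carries the sign
    of the a-vs-b comparison and includes a continuity correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    n1, n2 = len(a), len(b)
    u_a = float(res.statistic)
    u = min(u_a, n1 * n2 - u_a)
    mu = n1 * n2 / 2
    # tie-corrected variance
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        z = 0.0
    else:
        diff = u_a - mu
        z = (diff - 0.5 * np.sign(diff)) / math.sqrt(sigma2) if diff != 0 else 0.0
    return TestResult("mann_whitney_u", u, float(res.pvalue), n=n, extra={"z": z})


def welch_anova(*groups) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA with Welch-Satterthwaite df."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    gs = [np.asarray(g, float) for g in groups]
    if any(len(g) < 2 for g in gs):
        raise ValueError("each group needs n >= 2")
    k = len(gs)
    ns = np.array([len(g) for g in gs], float)
    means = np.array([g.mean() for g in gs])
    variances = np.array([g.var(ddof=1) for g in gs])
    w = ns / variances
    grand = (w * means).sum() / w.sum()
    num = ((w * (means - grand) ** 2).sum()) / (k - 1)
    h = ((1 - w / w.sum()) ** 2 / (ns - 1)).sum()
    den = 1 + 2 * (k - 2) / (k**2 - 1) * h
    f = num / den
    df1 = k - 1
    df2 = (k**2 - 1) / (3 * h)
    p = float(stats.f.sf(f, df1, df2))
    return TestResult("welch_f", float(f), p, df=(df1, float(df2)), n=int(ns.sum()))


def growth_check(heights_t0, heights_t1, ids_t0=None, ids_t1=None,
                 paired: bool = True) -> TestResult:
    """Determinate-growth comparison of shell heights at two time points.

    With ids supplied, specimens are matched by id before the paired test;
    the mean height change with a 95% CI is attached to the result.
    """
    a = np.asarray(heights_t0, float)
    b = np.asarray(heights_t1, float)
    if ids_t0 is not None or ids_t1 is not None:
        s0 = pd.Series(a, index=list(ids_t0))
        s1 = pd.Series(b, index=list(ids_t1))
        common = s0.index.intersection(s1.index)
        if len(common) != len(s0) or len(common) != len(s1):
            raise ValueError("unmatched specimen ids between time points")
        a = s0.loc[common].to_numpy()
        b = s1.loc[common].to_numpy()
    result = t_test(a, b, paired=paired)
    if paired:
        diff = b - a
        n = len(diff)
        se = diff.std(ddof=1) / math.sqrt(n) if n > 1 else 0.0
        half = stats.t.ppf(0.975, n - 1) * se if n > 1 else 0.0
        result.extra = {"mean_change": float(diff.mean()),
                        "ci95": (float(diff.mean() - half), float(diff.mean() + half))}
    return result


def whorl_height_screen(shell_height, whorls, threshold_rs: float = 0.5) -> TestResult:
    """Decide whether whorl count should be dropped from analyses that
    already include shell height.

    Whorl number and height measure overlapping aspects of size; whorls are
    excluded whenever their Spearman correlation with height reaches
    ``threshold_rs``.  The returned result carries the correlation and an
    ``exclude_whorls`` flag in ``extra``.
    """
    res = rank_correlation(shell_height, whorls, method="spearman")
    res.extra = {"exclude_whorls": bool(abs(res.statistic) >= threshold_rs),
                 "threshold_rs": threshold_rs}
    return res


def screen_collinear(table: pd.DataFrame, threshold_tau: float = 0.38,
                     drop_map: dict[str, str] | None = None):
    """Greedy collinearity screen on Kendall's tau.

    Every pair of numeric columns with |tau| >= ``threshold_tau`` is flagged.
    For a flagged pair the victim is taken from ``drop_map`` (victim ->
    retained partner) when provided; otherwise the later column in table
    order is dropped.  Returns (retained column list, list of
    (dropped, kept, tau) records).
    """
    if not 0 < threshold_tau <= 1:
        raise ValueError("threshold_tau must be in (0, 1]")
    cols = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    if len(cols) < 2:
        raise ValueError("need at least two numeric columns")
    dropped: list[tuple[str, str, float]] = []
    out = set()
    for i, ci in enumerate(cols):
        for cj in cols[i + 1:]:
            if ci in out or cj in out:
                continue
            tau = stats.kendalltau(table[ci], table[cj]).statistic
            if abs(tau) >= threshold_tau:
                if drop_map and ci in drop_map and drop_map[ci] == cj:
                    victim, kept = ci, cj
                elif drop_map and cj in drop_map and drop_map[cj] == ci:
                    victim, kept = cj, ci
                else:
                    victim, kept = cj, ci
                out.add(victim)
                dropped.append((victim, kept, float(tau)))
    retained = [c for c in cols if c not in out]
    return retained, dropped
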