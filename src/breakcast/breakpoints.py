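"""Chow-test structural-break detection at year junctions.

The Chow test asks whether the regression coefficients of two adjacent time
periods are identical.  Each segment (one calendar year, 12 monthly points)
is fit by ordinary least squares on an intercept plus the global month index,
and the pooled 24 points are fit once more.  With residual sums of squares
RSS_A, RSS_B and RSS_pooled and k regressors,

    F = [(RSS_pooled - RSS_A - RSS_B) / k] / [(RSS_A + RSS_B) / (n_A + n_B - 2k)]

is referred to an F(k, n_A + n_B - 2k) distribution.  A rejected junction is
then classified by where the series settles: if, a forecast horizon after
the junction, the level has returned to the pre-junction level the break was
a transient *sharp interruption*; if it stayed away it was a *level shift*.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .series import MonthlySeries

__all__ = ["BreakReport", "chow_test", "scan_series", "classify_scenario"]


@dataclass(frozen=True)
class BreakReport:
    """Chow-test outcome at one junction (first month of the later year)."""

    junction: int          # month index of the later segment's first month
    F: float
    p: float
    reject: bool
    scenario: str = "none"  # "none" | "sharp_interruption" | "level_shift" | "indeterminate"


def _ols_rss(t: np.ndarray, y: np.ndarray, with_trend: bool) -> float:
    X = np.column_stack([np.ones_like(t, dtype=float)] + ([t] if with_trend else []))
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def chow_test(
    segment_a: np.ndarray,
    segment_b: np.ndarray,
    alpha: float = 0.05,
    junction: int = 12,
    with_trend: bool = True,
) -> BreakReport:
    """Chow F test for equality of the two segments' regression coefficients.

    ``segment_a`` and ``segment_b`` are consecutive 12-month blocks; the
    regressor is the global month index (so the fitted lines share a time
    axis).  ``with_trend=False`` drops the slope and tests intercepts only.
    Degenerate noise-free cases are closed off explicitly: all three RSS zero
    means one coherent line (F = 0, no break); zero within-segment RSS with
    pooled misfit is a sure break (p = 0).
    """
    a = np.asarray(segment_a, dtype=float)
    b = np.asarray(segment_b, dtype=float)
    if a.shape != (12,) or b.shape != (12,):
        raise ValueError("chow_test expects two 12-month segments")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in Chow segments")

    k = 2 if with_trend else 1
    n_a = n_b = 12
    t_a = np.arange(junction - 12, junction, dtype=float)
    t_b = np.arange(junction, junction + 12, dtype=float)
    rss_a = _ols_rss(t_a, a, with_trend)
    rss_b = _ols_rss(t_b, b, with_trend)
    rss_p = _ols_rss(np.concatenate([t_a, t_b]), np.concatenate([a, b]), with_trend)

    df2 = n_a + n_b - 2 * k
    within = rss_a + rss_b
    scale = max(1.0, rss_p)
    if within <= 1e-12 * scale:
        if rss_p <= 1e-12:
            F, p = 0.0, 1.0            # one exact line through all 24 points
        else:
            F, p = np.inf, 0.0         # two exact but different lines
    else:
        F = ((rss_p - within) / k) / (within / df2)
        F = max(F, 0.0)
        p = float(stats.f.sf(F, k, df2))
    return BreakReport(junction=junction, F=float(F), p=p, reject=p < alpha)


def scan_series(
    series: MonthlySeries, alpha: float = 0.05, with_trend: bool = True
) -> list[BreakReport]:
    """Chow test at every adjacent-year junction of a whole-year series."""
    n = len(series)
    if n % 12 != 0:
        raise ValueError("scan_series expects a whole-year series")
    years = n // 12
    reports = []
    for y in range(1, years):
        j = 12 * y
        reports.append(chow_test(
            series.values[j - 12 : j], series.values[j : j + 12],
            alpha=alpha, junction=j, with_trend=with_trend,
        ))
    return reports


def classify_scenario(
    series: MonthlySeries,
    junction_reports: list[BreakReport],
    horizon: int = 12,
    tol: float = 1.0,
) -> list[BreakReport]:
    """Label each rejected junction as sharp interruption vs level shift.

    For a rejected junction at month m the pre-break level is the mean of the
    12 months before m and the settled post-break level is the mean of months
    m+horizon .. m+horizon+11 (or whatever remains, if at least 6 months).
    If the settled level is within ``tol`` pre-break residual SDs of the
    pre-break level, the series came back: ``sharp_interruption``; otherwise
    it stayed away: ``level_shift``.  With fewer than 6 settled months the
    label is ``indeterminate``.
    """
    values = series.values
    n = values.size
    out = []
    for rep in junction_reports:
        if not rep.reject:
            out.append(rep)
            continue
        m = rep.junction
        pre = values[m - 12 : m]
        far = values[m + horizon : m + horizon + 12]
        if far.size < 6:
            out.append(replace(rep, scenario="indeterminate"))
            continue
        # residual SD around the pre-break linear fit, floored for noise-free input
        t_pre = np.arange(m - 12, m, dtype=float)
        X = np.column_stack([np.ones(12), t_pre])
        coef, *_ = np.linalg.lstsq(X, pre, rcond=None)
        sd_pre = float(np.sqrt(np.mean((pre - X @ coef) ** 2)))
        threshold = tol * max(sd_pre, 1e-12)
        label = ("sharp_interruption"
                 if abs(float(far.mean()) - float(pre.mean())) <= threshold
                 else "level_shift")
        out.append(replace(rep, scenario=label))
    return out
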