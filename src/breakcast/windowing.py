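"""Sliding 10-year windows with 7/1/2-year train/validation/test splits.

A span of Y whole years yields Y - 10 + 1 overlapping 10-year windows moved
one year at a time.  Within each window the first 84 months train the models,
the next 12 validate hyperparameter/order choices, and the final 24 are held
out for testing.  Each window is labelled *stable* when the Chow test rejects
at none of its three late junctions (years 7-8, 8-9, 9-10) and *unstable*
otherwise; the scenario label of an unstable window comes from its rejected
junctions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import pandas as pd

from .breakpoints import BreakReport, chow_test, classify_scenario
from .series import MonthlySeries

__all__ = ["WindowSample", "make_windows", "label_windows"]

TRAIN_MONTHS, VAL_MONTHS, TEST_MONTHS = 84, 12, 24
WINDOW_MONTHS = TRAIN_MONTHS + VAL_MONTHS + TEST_MONTHS


@dataclass(frozen=True)
class WindowSample:
    """One 10-year subsample of one group's series."""

    group: str
    start_year: int
    series: MonthlySeries                    # the full 120-month window
    junction_reports: tuple[BreakReport, ...] = ()
    stability: str = "unlabelled"            # "stable" | "unstable" | "unlabelled"
    scenario: str = "none"

    @property
    def train(self) -> MonthlySeries:
        return self.series.slice(0, TRAIN_MONTHS)

    @property
    def validation(self) -> MonthlySeries:
        return self.series.slice(TRAIN_MONTHS, VAL_MONTHS)

    @property
    def test(self) -> MonthlySeries:
        return self.series.slice(TRAIN_MONTHS + VAL_MONTHS, TEST_MONTHS)

    @property
    def history(self) -> MonthlySeries:
        """Train plus validation months — the history test forecasts condition on."""
        return self.series.slice(0, TRAIN_MONTHS + VAL_MONTHS)


def make_windows(
    series: MonthlySeries, window_years: int = 10, step_years: int = 1
) -> list[WindowSample]:
    """Cut a whole-year series into calendar-aligned sliding windows."""
    n = len(series)
    if n % 12 != 0:
        raise ValueError("make_windows expects a whole-year series")
    span_years = n // 12
    if span_years < window_years:
        warnings.warn(
            f"span of {span_years} years shorter than window of {window_years}: "
            "no windows", stacklevel=2,
        )
        return []
    out = []
    for k in range(0, span_years - window_years + 1, step_years):
        sub = series.slice(12 * k, 12 * window_years)
        out.append(WindowSample(
            group=series.label,
            start_year=int(sub.start.year),
            series=sub,
        ))
    return out


def label_windows(
    windows: list[WindowSample],
    alpha: float = 0.05,
    with_trend: bool = True,
    scenario_rule: str = "earliest",
) -> list[WindowSample]:
    """Chow-test the three late junctions of each window and label stability.

    Only the junctions between years 7-8, 8-9 and 9-10 are tested: a break
    wholly inside the training years does not make the validation/test
    segments a non-smooth extension of training.  The window's scenario is
    the label of its earliest rejected junction (first shock dominates the
    test period) unless ``scenario_rule="latest"``.
    """
    if scenario_rule not in ("earliest", "latest"):
        raise ValueError("scenario_rule must be 'earliest' or 'latest'")
    labelled = []
    for w in windows:
        vals = w.series.values
        reports = []
        for j in (TRAIN_MONTHS, TRAIN_MONTHS + 12, TRAIN_MONTHS + 24):
            reports.append(chow_test(
                vals[j - 12 : j], vals[j : j + 12],
                alpha=alpha, junction=j, with_trend=with_trend,
            ))
        reports = classify_scenario(w.series, reports)
        rejected = [r for r in reports if r.reject]
        stability = "stable" if not rejected else "unstable"
        if rejected:
            pick = rejected[0] if scenario_rule == "earliest" else rejected[-1]
            scenario = pick.scenario
        else:
            scenario = "none"
        labelled.append(replace(
            w, junction_reports=tuple(reports), stability=stability, scenario=scenario,
        ))
    return labelled


def windows_to_frame(windows: list[WindowSample]) -> pd.DataFrame:
    """Window inventory (group, start_year, stability, scenario, junction p's)."""
    rows = []
    for w in windows:
        row = {
            "group": w.group,
            "start_year": w.start_year,
            "stability": w.stability,
            "scenario": w.scenario,
        }
        for i, r in enumerate(w.junction_reports):
            row[f"p_junction_{i + 1}"] = r.p
        rows.append(row)
    return pd.DataFrame(rows)
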