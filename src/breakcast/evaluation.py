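"""SMAPE scoring, stability-stratified aggregation and paired model comparison.

SMAPE is the mean-of-ratios symmetric mean absolute percentage error with the
half-sum denominator,

    SMAPE = (100 / n) * sum_t |F_t - A_t| / ((|A_t| + |F_t|) / 2),

ranging from 0 to 200% for nonnegative series; a term with A_t = F_t = 0
contributes 0 (continuous extension).  Model comparisons are two-sided paired
t tests on per-window SMAPE differences: all models score the same windows,
so pairing by window is the appropriate design.  No multiple-comparison
correction is applied across model pairs; p-values are reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["smape", "ScoreTable", "score_windows", "compare_models", "scenario_report"]


def smape(actual, forecast) -> float:
    """Symmetric mean absolute percentage error, in percent (0..200)."""
    a = np.asarray(actual, dtype=float)
    f = np.asarray(forecast, dtype=float)
    if a.shape != f.shape or a.ndim != 1:
        raise ValueError(f"shape mismatch: actual {a.shape} vs forecast {f.shape}")
    if a.size == 0:
        raise ValueError("empty input")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(f))):
        raise ValueError("non-finite values")
    denom = (np.abs(a) + np.abs(f)) / 2.0
    terms = np.zeros_like(a)
    nz = denom > 0
    terms[nz] = np.abs(f[nz] - a[nz]) / denom[nz]
    return float(100.0 * terms.mean())


@dataclass(frozen=True)
class ScoreTable:
    """Long-format per-window, per-model test SMAPEs."""

    rows: pd.DataFrame   # columns: group, start_year, stability, scenario, model, test_smape

    def __post_init__(self) -> None:
        required = {"group", "start_year", "stability", "scenario", "model", "test_smape"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"score table missing columns {sorted(missing)}")
        dup = self.rows.duplicated(subset=["group", "start_year", "model"])
        if dup.any():
            raise ValueError("duplicate (window, model) rows in score table")

    def aggregates(self) -> pd.DataFrame:
        """Mean SMAPE per model within each stability class (window weight 1)."""
        return (self.rows.groupby(["stability", "model"], as_index=False)["test_smape"]
                .mean().rename(columns={"test_smape": "mean_smape"}))

    def pivot(self, stratum: str | None = None) -> pd.DataFrame:
        """Windows x models matrix of SMAPEs, optionally within one stability class."""
        df = self.rows if stratum is None else self.rows[self.rows["stability"] == stratum]
        return df.pivot_table(index=["group", "start_year"], columns="model",
                              values="test_smape")


def score_windows(windows, results) -> ScoreTable:
    """Score every (window, model) forecast on the 24-month test segment.

    ``results`` maps (group, start_year, model) -> 24 point forecasts on the
    original scale.  Scoring reads only the test segment; validation and
    training values play no role here.
    """
    rows = []
    for w in windows:
        actual = w.test.values
        for (g, y, model), forecast in results.items():
            if g != w.group or y != w.start_year:
                continue
            rows.append({
                "group": w.group, "start_year": w.start_year,
                "stability": w.stability, "scenario": w.scenario,
                "model": model,
                "test_smape": smape(actual, np.asarray(forecast)[: actual.size]),
            })
    if not rows:
        raise ValueError("no (window, model) forecasts to score")
    return ScoreTable(pd.DataFrame(rows))


@dataclass(frozen=True)
class PairedComparison:
    model_a: str
    model_b: str
    stratum: str
    n: int
    mean_diff: float   # mean(SMAPE_a - SMAPE_b)
    t: float
    df: int
    p: float
    flag: str = ""


def compare_models(
    table: ScoreTable, model_a: str, model_b: str, stratum: str | None = None
) -> PairedComparison:
    """Two-sided paired t test of SMAPE between two models on shared windows."""
    wide = table.pivot(stratum)
    for m in (model_a, model_b):
        if m not in wide.columns:
            raise ValueError(f"model {m!r} absent from score table")
    pair = wide[[model_a, model_b]].dropna()
    n = len(pair)
    if n < 3:
        raise ValueError(f"insufficient windows for paired test: {n} < 3")
    d = (pair[model_a] - pair[model_b]).to_numpy()
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    label = stratum if stratum is not None else "all"
    if sd == 0.0:
        # zero-variance differences: identical vectors -> no evidence (p = 1);
        # constant nonzero offset -> certain difference (p = 0), flagged
        if mean_diff == 0.0:
            return PairedComparison(model_a, model_b, label, n, 0.0, 0.0, n - 1, 1.0,
                                    flag="zero-variance")
        return PairedComparison(model_a, model_b, label, n, mean_diff,
                                np.inf if mean_diff > 0 else -np.inf, n - 1, 0.0,
                                flag="zero-variance")
    t = mean_diff / (sd / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return PairedComparison(model_a, model_b, label, n, mean_diff, float(t), n - 1, p)


def scenario_report(table: ScoreTable) -> pd.DataFrame:
    """Per-(group, scenario) mean SMAPE of every model, best model(s) flagged.

    Ties on the minimum (to 2 decimals, the reporting precision) are flagged
    jointly in the ``best`` column.
    """
    df = (table.rows.groupby(["group", "scenario", "model"], as_index=False)
          ["test_smape"].mean())
    wide = df.pivot_table(index=["group", "scenario"], columns="model",
                          values="test_smape")
    best = []
    for _, row in wide.iterrows():
        r = row.round(2)
        best.append(",".join(sorted(r.index[r == r.min()])))
    wide = wide.copy()
    wide["best"] = best
    return wide.reset_index()
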