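"""Monthly time-series container and CSV panel I/O.

The package works on regularly spaced monthly series — disease incidence
(per 100,000 population per month) and unemployment (percent).  A panel is
a set of such series sharing one monthly calendar, stored as CSV with a
``month`` column (ISO ``YYYY-MM``) and one numeric column per group.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["MonthlySeries", "read_series", "write_series"]


@dataclass(frozen=True)
class MonthlySeries:
    """A labelled, regularly spaced monthly value sequence.

    Parameters
    ----------
    label : str
        Group name, e.g. ``"20-29"`` or ``"overall"``.
    start : pd.Period
        Calendar month of the first value (monthly frequency).
    values : np.ndarray
        One value per month, finite, no gaps.
    units : str
        ``"per 100,000"`` for incidence, ``"percent"`` for unemployment.
    """

    label: str
    start: pd.Period
    values: np.ndarray
    units: str = "per 100,000"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"series {self.label!r} contains non-finite values")
        object.__setattr__(self, "values", vals)
        start = pd.Period(self.start, freq="M")
        object.__setattr__(self, "start", start)

    def __len__(self) -> int:
        return self.values.size

    @property
    def index(self) -> pd.PeriodIndex:
        return pd.period_range(self.start, periods=len(self), freq="M")

    @property
    def months(self) -> np.ndarray:
        """Calendar month (1..12) of every time point."""
        return self.index.month.to_numpy()

    def slice(self, first: int, n: int, label: str | None = None) -> "MonthlySeries":
        """Contiguous sub-series of ``n`` months starting at offset ``first``."""
        if first < 0 or first + n > len(self):
            raise IndexError(
                f"slice [{first}, {first + n}) out of range for length {len(self)}"
            )
        return MonthlySeries(
            label=label or self.label,
            start=self.start + first,
            values=self.values[first : first + n],
            units=self.units,
        )

    def with_values(self, values: np.ndarray) -> "MonthlySeries":
        return replace(self, values=np.asarray(values, dtype=float))

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.index, name=self.label)


def write_series(path, series: Sequence[MonthlySeries]) -> None:
    """Write series sharing one calendar to CSV (``month,<g1>,<g2>,...``)."""
    if not series:
        raise ValueError("no series to write")
    idx = series[0].index
    for s in series[1:]:
        if not s.index.equals(idx):
            raise ValueError(
                f"series {s.label!r} calendar differs from {series[0].label!r}"
            )
    df = pd.DataFrame({s.label: s.values for s in series})
    df.insert(0, "month", idx.strftime("%Y-%m"))
    df.to_csv(path, index=False, float_format="%.17g")


_READ_KWARGS = {"float_precision": "round_trip"}


def read_series(path, units: str = "per 100,000") -> list[MonthlySeries]:
    """Read a monthly panel CSV back into :class:`MonthlySeries` objects.

    Months must be strictly consecutive; a gap or a non-numeric cell is an
    explicit error naming the offending month or cell.
    """
    df = pd.read_csv(path, dtype={"month": str}, **_READ_KWARGS)
    if "month" not in df.columns:
        raise ValueError(f"{path}: expected a 'month' column")
    if df.empty:
        raise ValueError(f"{path}: no rows")
    try:
        months = pd.PeriodIndex(df["month"].to_list(), freq="M")
    except Exception as exc:  # malformed month label
        raise ValueError(f"{path}: unparseable month value ({exc})") from exc
    expected = pd.period_range(months[0], periods=len(months), freq="M")
    if not months.equals(expected):
        diff = expected.difference(months)
        missing = diff[0].strftime("%Y-%m") if len(diff) else months[0].strftime("%Y-%m")
        raise ValueError(f"{path}: missing month {missing} (months must be consecutive)")
    out = []
    for col in df.columns:
        if col == "month":
            continue
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = np.nonzero(~np.isfinite(vals))[0]
        if bad.size:
            row = int(bad[0])
            raise ValueError(
                f"{path}: non-numeric cell at row {row + 2}, column {col!r} "
                f"(month {months[row].strftime('%Y-%m')})"
            )
        out.append(MonthlySeries(label=col, start=months[0], values=vals, units=units))
    return out
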