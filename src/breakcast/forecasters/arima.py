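"""Univariate ARIMA forecasting with validation-SMAPE order selection.

The series is deseasonalized with a training-only classical seasonal profile,
modelled as ARIMA(p, 1, q) with trend "n" (no drift) or "c" (constant drift),
and forecasts are reseasonalized.  Orders p in 0..3 and q in 0..2 are searched
and the configuration with the lowest validation SMAPE wins (ties prefer the
more parsimonious p+q, then "n" over "c").  Parameters are estimated on the
training segment only; test-period forecasts are produced by conditioning the
selected parameter vector on the train+validation history.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np

from ..evaluation import smape
from ..preprocessing import SeasonalProfile, decompose_additive, deseasonalize
from ..series import MonthlySeries
from .base import ForecastResult

logger = logging.getLogger(__name__)

__all__ = ["ArimaOrder", "default_arima_grid", "fit_arima", "FittedArima"]


@dataclass(frozen=True)
class ArimaOrder:
    p: int
    q: int
    trend: str = "n"   # "n" no drift | "c" constant drift
    d: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 3 and 0 <= self.q <= 2):
            raise ValueError(f"order out of range: p={self.p}, q={self.q}")
        if self.trend not in ("n", "c"):
            raise ValueError(f"trend must be 'n' or 'c', got {self.trend!r}")

    @property
    def sort_key(self):
        return (self.p + self.q, self.trend == "c", self.p, self.q)


def default_arima_grid(p_max: int = 3, q_max: int = 2,
                       trends: tuple[str, ...] = ("n", "c")) -> list[ArimaOrder]:
    return [ArimaOrder(p, q, tr)
            for p, q, tr in product(range(p_max + 1), range(q_max + 1), trends)]


def _fit_one(values: np.ndarray, order: ArimaOrder):
    from statsmodels.tsa.arima.model import ARIMA

    model = ARIMA(values, order=(order.p, order.d, order.q), trend=order.trend,
                  enforce_stationarity=True, enforce_invertibility=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit()


class FittedArima:
    """Selected ARIMA order with its train-only parameter estimates."""

    def __init__(self, order: ArimaOrder, train_result, history_deseas: np.ndarray,
                 profile: SeasonalProfile, history: MonthlySeries,
                 validation_smape: float):
        self.order = order
        self._res = train_result
        self._history_deseas = history_deseas
        self._profile = profile
        self._history = history
        self.validation_smape = validation_smape

    def predict(self, horizon: int = 24) -> ForecastResult:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            applied = self._res.apply(self._history_deseas, refit=False)
            f = np.asarray(applied.forecast(steps=horizon))
        months = ((self._history.start + len(self._history)).month - 1
                  + np.arange(horizon)) % 12 + 1
        f = f + self._profile.for_months(months)
        return ForecastResult(
            model="arima", target="incidence", forecast=f,
            chosen_config={"p": self.order.p, "d": self.order.d,
                           "q": self.order.q, "trend": self.order.trend},
            validation_smape=self.validation_smape,
        )


def fit_arima(
    train: MonthlySeries,
    validation: MonthlySeries,
    grid: list[ArimaOrder] | None = None,
    profile: SeasonalProfile | None = None,
    seasonal_adjust: bool = True,
) -> FittedArima:
    """Grid-search ARIMA(p, 1, q) x trend on the validation year.

    ``profile`` overrides the seasonal profile (e.g. ``SeasonalProfile.zero()``
    to disable adjustment in tests); by default it is estimated from the
    training segment alone.
    """
    if grid is None:
        grid = default_arima_grid()
    if profile is None:
        profile = (decompose_additive(train)[1] if seasonal_adjust
                   else SeasonalProfile.zero())
    train_adj = deseasonalize(train, profile)
    val_seasonal = profile.for_months(validation.months)

    candidates = []
    for order in grid:
        try:
            res = _fit_one(train_adj.values, order)
            fcast = np.asarray(res.forecast(steps=len(validation))) + val_seasonal
            if not np.all(np.isfinite(fcast)):
                raise ValueError("non-finite forecast")
            score = smape(validation.values, fcast)
        except Exception as exc:
            logger.info("arima config %s skipped: %s", order, exc)
            continue
        candidates.append((score, order.sort_key, order, res))
    if not candidates:
        raise RuntimeError("all ARIMA configurations failed to fit")
    candidates.sort(key=lambda c: (c[0], c[1]))
    best_score, _, best_order, best_res = candidates[0]

    history = MonthlySeries(train.label, train.start,
                            np.concatenate([train.values, validation.values]),
                            units=train.units)
    history_deseas = deseasonalize(history, profile).values
    return FittedArima(best_order, best_res, history_deseas, profile, history,
                       validation_smape=best_score)
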