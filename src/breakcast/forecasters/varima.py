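"""Bivariate VARIMA forecasting of (incidence, unemployment).

Both outcomes are deseasonalized with training-only profiles, first-differenced
(both series are treated as integrated of order 1), and modelled jointly as a
VARMA(p, q) with optional constant, so each variable's equation adjusts to
lagged values of the other.  Order selection mirrors the univariate ARIMA
search: lowest incidence SMAPE on the validation year, ties preferring
parsimony and "n" over "c".  Difference forecasts are integrated back from the
last observed pre-forecast level and reseasonalized.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from ..evaluation import smape
from ..preprocessing import SeasonalProfile, decompose_additive, deseasonalize
from ..series import MonthlySeries
from .arima import ArimaOrder, default_arima_grid
from .base import ForecastResult

logger = logging.getLogger(__name__)

__all__ = ["fit_varima", "FittedVarima"]


def _fit_varmax(diffs: np.ndarray, order: ArimaOrder):
    from statsmodels.tsa.statespace.varmax import VARMAX

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = VARMAX(diffs, order=(order.p, order.q), trend=order.trend,
                       error_cov_type="unstructured")
        return model.fit(disp=False, maxiter=100)


def _forecast_diffs(res, order: ArimaOrder, diffs: np.ndarray, steps: int) -> np.ndarray:
    """Difference-scale forecasts; the (0,0) model is handled in closed form."""
    if order.p == 0 and order.q == 0:
        mu = diffs.mean(axis=0) if order.trend == "c" else np.zeros(diffs.shape[1])
        return np.tile(mu, (steps, 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        applied = res.apply(diffs, refit=False) if res is not None else None
        return np.asarray(applied.forecast(steps=steps))


class FittedVarima:
    """Selected VARMA order with train-only estimates for the differenced pair."""

    def __init__(self, order: ArimaOrder, train_result,
                 history_levels: np.ndarray, profiles: tuple[SeasonalProfile, SeasonalProfile],
                 history: MonthlySeries, validation_smape: float):
        self.order = order
        self._res = train_result
        self._levels = history_levels          # deseasonalized levels, (n, 2)
        self._profiles = profiles
        self._history = history
        self.validation_smape = validation_smape

    def predict(self, horizon: int = 24) -> ForecastResult:
        diffs = np.diff(self._levels, axis=0)
        dfc = _forecast_diffs(self._res, self.order, diffs, horizon)
        levels = self._levels[-1] + np.cumsum(dfc, axis=0)
        months = ((self._history.start + len(self._history)).month - 1
                  + np.arange(horizon)) % 12 + 1
        inc = levels[:, 0] + self._profiles[0].for_months(months)
        une = levels[:, 1] + self._profiles[1].for_months(months)
        return ForecastResult(
            model="varima", target="incidence", forecast=inc,
            chosen_config={"p": self.order.p, "d": 1, "q": self.order.q,
                           "trend": self.order.trend},
            validation_smape=self.validation_smape,
            extra_targets={"unemployment": une},
        )


def fit_varima(
    train: tuple[MonthlySeries, MonthlySeries],
    validation: tuple[MonthlySeries, MonthlySeries],
    grid: list[ArimaOrder] | None = None,
    profiles: tuple[SeasonalProfile, SeasonalProfile] | None = None,
    seasonal_adjust: bool = True,
) -> FittedVarima:
    """Grid-search VARMA(p, q) x trend on the aligned bivariate window.

    ``train`` and ``validation`` are (incidence, unemployment) pairs; scoring
    uses the incidence SMAPE only, but both outcomes are forecast jointly.
    """
    inc_tr, une_tr = train
    inc_va, une_va = validation
    if len(inc_tr) != len(une_tr) or len(inc_va) != len(une_va):
        raise ValueError("incidence and unemployment segments must be aligned")
    if grid is None:
        grid = default_arima_grid()
    if profiles is None:
        if seasonal_adjust:
            profiles = (decompose_additive(inc_tr)[1], decompose_additive(une_tr)[1])
        else:
            profiles = (SeasonalProfile.zero(), SeasonalProfile.zero())

    levels_tr = np.column_stack([deseasonalize(inc_tr, profiles[0]).values,
                                 deseasonalize(une_tr, profiles[1]).values])
    diffs_tr = np.diff(levels_tr, axis=0)
    val_seasonal = profiles[0].for_months(inc_va.months)

    candidates = []
    for order in grid:
        try:
            res = None
            if not (order.p == 0 and order.q == 0):
                res = _fit_varmax(diffs_tr, order)
                dfc = np.asarray(res.forecast(steps=len(inc_va)))
            else:
                dfc = _forecast_diffs(None, order, diffs_tr, len(inc_va))
            levels = levels_tr[-1] + np.cumsum(dfc, axis=0)
            fcast = levels[:, 0] + val_seasonal
            if not np.all(np.isfinite(fcast)):
                raise ValueError("non-finite forecast")
            score = smape(inc_va.values, fcast)
        except Exception as exc:
            logger.info("varima config %s skipped: %s", order, exc)
            continue
        candidates.append((score, order.sort_key, order, res))
    if not candidates:
        raise RuntimeError("all VARIMA configurations failed to fit")
    candidates.sort(key=lambda c: (c[0], c[1]))
    best_score, _, best_order, best_res = candidates[0]

    history = MonthlySeries(inc_tr.label, inc_tr.start,
                            np.concatenate([inc_tr.values, inc_va.values]),
                            units=inc_tr.units)
    hist_levels = np.column_stack([
        np.concatenate([levels_tr[:, 0],
                        deseasonalize(inc_va, profiles[0]).values]),
        np.concatenate([levels_tr[:, 1],
                        deseasonalize(une_va, profiles[1]).values]),
    ])
    return FittedVarima(best_order, best_res, hist_levels, profiles, history,
                        validation_smape=best_score)
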