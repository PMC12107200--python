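"""Shared fit/validate/predict contract for all four forecasters.

Every model is fit on the 84-month training segment, tuned by symmetric mean
absolute percentage error on the 12-month validation segment, and then asked
for up to 24 monthly point forecasts that follow the validation segment.
Forecasts are always returned on the original (reseasonalized) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Protocol

import numpy as np

from ..series import MonthlySeries

__all__ = ["ForecastResult", "FittedForecaster"]


@dataclass(frozen=True)
class ForecastResult:
    """Point forecasts from one fitted model for one window."""

    model: str
    target: str
    forecast: np.ndarray            # horizon monthly values, original scale
    chosen_config: dict[str, Any]
    validation_smape: float
    extra_targets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.forecast, dtype=float)
        if not np.all(np.isfinite(f)):
            raise ValueError(f"{self.model}: non-finite forecasts")
        object.__setattr__(self, "forecast", f)


class FittedForecaster(Protocol):
    """What the pipeline needs from any fitted model."""

    def predict(self, horizon: int = 24) -> ForecastResult: ...
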