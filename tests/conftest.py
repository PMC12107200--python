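"""Shared fixtures: small synthetic series built programmatically."""

import numpy as np
import pytest

from breakcast.series import MonthlySeries
from breakcast.synthetic import ScenarioSpec, generate_group


@pytest.fixture
def noise_free_spec():
    """Deterministic scenario: seasonal + trend only."""
    return ScenarioSpec(label="det", years=10, seed=0, noise_sd=0.0,
                        u_noise_sd=0.0, ar_coef=0.0, coupling=(0.0, 0.0))


@pytest.fixture
def default_pair():
    """One realistic coupled (incidence, unemployment) pair, 10 years."""
    return generate_group(ScenarioSpec(label="g", years=10, seed=3))


@pytest.fixture
def ar1_series():
    """AR(1) series factory around a constant level, no seasonality."""

    def make(phi: float = 0.8, mu: float = 10.0, n: int = 96, seed: int = 5,
             sigma: float = 1.0) -> MonthlySeries:
        rng = np.random.default_rng(seed)
        e = rng.normal(0, sigma, n)
        y = np.empty(n)
        y[0] = mu + e[0]
        for t in range(1, n):
            y[t] = mu + phi * (y[t - 1] - mu) + e[t]
        return MonthlySeries("ar1", "2002-01", y)

    return make
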