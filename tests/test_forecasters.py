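"""Forecaster contracts: closed-form oracles, selection, TFT mechanisms."""

import numpy as np
import pytest

from breakcast.evaluation import smape
from breakcast.forecasters import (ArimaOrder, TftConfig, default_arima_grid,
                                   extend_history, fit_arima, fit_tft,
                                   fit_varima)
from breakcast.forecasters._autodiff import Tensor
from breakcast.forecasters.tft import smape_loss
from breakcast.preprocessing import SeasonalProfile
from breakcast.series import MonthlySeries
from breakcast.synthetic import ScenarioSpec, generate_group
from breakcast.windowing import make_windows
from breakcast.pipeline import _pair_window

ZERO = SeasonalProfile.zero()


def _ms(values, start="2002-01", label="x"):
    return MonthlySeries(label, start, np.asarray(values, dtype=float))


class TestArima:
    def test_constant_train_forecasts_constant(self):
        tr = _ms(np.full(84, 12.0))
        va = _ms(np.full(12, 12.0), start="2009-01")
        f = fit_arima(tr, va, grid=[ArimaOrder(0, 0, "n")], profile=ZERO)
        r = f.predict(24)
        np.testing.assert_allclose(r.forecast, 12.0, atol=1e-8)
        assert smape(np.full(24, 12.0), r.forecast) == pytest.approx(0.0, abs=1e-8)

    def test_ar1_forecasts_match_closed_form(self, ar1_series):
        s = ar1_series(phi=0.8, n=96)
        tr, va = s.slice(0, 84), s.slice(84, 12)
        f = fit_arima(tr, va, grid=[ArimaOrder(1, 0, "c", d=0)], profile=ZERO)
        r = f.predict(24)
        phi_hat = f._res.params[f._res.param_names.index("ar.L1")]
        mu_hat = f._res.params[f._res.param_names.index("const")]
        y_T = s.values[95]
        closed = mu_hat + phi_hat ** np.arange(1, 25) * (y_T - mu_hat)
        np.testing.assert_allclose(r.forecast, closed, atol=1e-8)

    def test_random_walk_equals_naive_last_value(self, ar1_series):
        s = ar1_series(phi=0.5, n=96, seed=11)
        tr, va = s.slice(0, 84), s.slice(84, 12)
        f = fit_arima(tr, va, grid=[ArimaOrder(0, 0, "n", d=1)], profile=ZERO)
        r = f.predict(24)
        np.testing.assert_allclose(r.forecast, s.values[95], atol=1e-10)

    def test_horizon_requests_differ_only_by_truncation(self, default_pair):
        inc, _ = default_pair
        w = make_windows(inc)[0]
        f = fit_arima(w.train, w.validation, grid=default_arima_grid(1, 1))
        f12 = f.predict(12).forecast
        f24 = f.predict(24).forecast
        np.testing.assert_allclose(f12, f24[:12], atol=1e-10)

    def test_selection_detects_strong_dependence(self):
        """On a persistent AR(1) the search never settles on the naive model."""
        hits = 0
        for s in range(12):
            rng = np.random.default_rng(300 + s)
            n, mu = 132, 10.0
            y = np.empty(n)
            y[0] = mu
            e = rng.normal(0, 1, n)
            for t in range(1, n):
                y[t] = mu + 0.9 * (y[t - 1] - mu) + e[t]
            tr, va = _ms(y[:120]), _ms(y[120:], start="2012-01")
            grid = [ArimaOrder(p, q, tr_, d=0) for p in range(3) for q in range(2)
                    for tr_ in ("n", "c")]
            f = fit_arima(tr, va, grid=grid, profile=ZERO)
            hits += (f.order.p + f.order.q) >= 1
        assert hits > 6

    def test_tie_break_prefers_parsimony(self):
        assert ArimaOrder(0, 1, "n").sort_key < ArimaOrder(1, 1, "n").sort_key
        assert ArimaOrder(1, 0, "n").sort_key < ArimaOrder(1, 0, "c").sort_key


class TestVarima:
    def test_one_step_forecast_equals_matrix_recursion(self):
        rng = np.random.default_rng(7)
        A = np.array([[0.5, 0.2], [0.1, 0.6]])
        n = 97
        d = np.empty((n, 2))
        d[0] = [0.5, -0.3]
        eps = rng.normal(0, 1e-5, size=(n, 2))
        for t in range(1, n):
            d[t] = A @ d[t - 1] + eps[t]
        levels = np.empty((n + 1, 2))
        levels[0] = [10.0, 4.0]
        levels[1:] = levels[0] + np.cumsum(d, axis=0)
        tr = (_ms(levels[:85, 0]), _ms(levels[:85, 1]))
        va = (_ms(levels[85:97, 0], start="2009-02"),
              _ms(levels[85:97, 1], start="2009-02"))
        f = fit_varima(tr, va, grid=[ArimaOrder(1, 0, "n")],
                       profiles=(ZERO, ZERO))
        A_hat = f._res.coefficient_matrices_var[0]
        hand = levels[96] + A_hat @ (levels[96] - levels[95])
        r = f.predict(1)
        got = np.array([r.forecast[0], r.extra_targets["unemployment"][0]])
        np.testing.assert_allclose(got, hand, atol=1e-12)

    def test_coefficient_matrix_recovered_from_long_series(self):
        rng = np.random.default_rng(7)
        A = np.array([[0.5, 0.2], [0.1, 0.6]])
        n = 397
        d = np.empty((n, 2))
        d[0] = [0.5, -0.3]
        eps = rng.normal(0, 0.2, size=(n, 2))
        for t in range(1, n):
            d[t] = A @ d[t - 1] + eps[t]
        levels = np.empty((n + 1, 2))
        levels[0] = [10.0, 4.0]
        levels[1:] = levels[0] + np.cumsum(d, axis=0)
        tr = (_ms(levels[:385, 0]), _ms(levels[:385, 1]))
        va = (_ms(levels[385:397, 0], start="2034-02"),
              _ms(levels[385:397, 1], start="2034-02"))
        f = fit_varima(tr, va, grid=[ArimaOrder(1, 0, "n")], profiles=(ZERO, ZERO))
        assert np.abs(f._res.coefficient_matrices_var[0] - A).max() < 0.15

    def test_zero_coupling_close_to_univariate_arima(self):
        for seed in (700, 701, 702):
            inc, une = generate_group(ScenarioSpec(label="g", years=10, seed=seed,
                                                   coupling=(0.0, 0.0)))
            w = make_windows(inc)[0]
            uw = _pair_window(w, une)
            fa = fit_arima(w.train, w.validation, grid=[ArimaOrder(1, 0, "n")])
            fv = fit_varima((w.train, uw.train), (w.validation, uw.validation),
                            grid=[ArimaOrder(1, 0, "n")])
            gap = np.abs(fa.predict(24).forecast - fv.predict(24).forecast).mean()
            assert gap < 0.3  # same orders, block-diagonal limit

    def test_strong_coupling_helps_validation_accuracy(self):
        wins = 0
        for seed in range(12):
            inc, une = generate_group(ScenarioSpec(
                label="g", years=10, seed=800 + seed, coupling=(1.5, 0.01),
                u_ar_coef=0.92, u_noise_sd=0.35))
            w = make_windows(inc)[0]
            uw = _pair_window(w, une)
            fa = fit_arima(w.train, w.validation, grid=default_arima_grid(1, 1))
            fv = fit_varima((w.train, uw.train), (w.validation, uw.validation),
                            grid=default_arima_grid(1, 1))
            wins += fv.validation_smape <= fa.validation_smape
        assert wins > 6


class TestSmapeLoss:
    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        pred0 = rng.uniform(5, 15, size=(3, 6))
        actual = rng.uniform(5, 15, size=(3, 6))
        p = Tensor(pred0.copy())
        loss = smape_loss(p * 1.0, actual)
        loss.backward()
        num = np.zeros_like(pred0)
        eps = 1e-6
        for i in range(3):
            for j in range(6):
                up, dn = pred0.copy(), pred0.copy()
                up[i, j] += eps
                dn[i, j] -= eps
                num[i, j] = (smape_loss(Tensor(up), actual).data
                             - smape_loss(Tensor(dn), actual).data) / (2 * eps)
        np.testing.assert_allclose(p.grad, num, rtol=1e-5, atol=1e-8)

    def test_zero_at_equality_and_symmetric_in_sign_region(self):
        a = np.array([[3.0, 4.0]])
        assert smape_loss(Tensor(a), a).data == pytest.approx(0.0)


class TestTft:
    SMALL = TftConfig(hidden_size=8, attention_heads=2, encoder_length=24,
                      max_epochs=8, early_stop_patience=3, batch_size=64, seed=1)

    def test_fixed_seed_runs_are_bit_reproducible(self, default_pair):
        inc, _ = default_pair
        w = make_windows(inc)[0]
        r1 = fit_tft(w.train, w.validation, config=self.SMALL).predict(24)
        r2 = fit_tft(w.train, w.validation, config=self.SMALL).predict(24)
        np.testing.assert_array_equal(r1.forecast, r2.forecast)

    def test_early_stopping_halts_exactly_patience_after_best(self, default_pair):
        inc, _ = default_pair
        w = make_windows(inc)[0]
        # learning rate zero: validation loss constant, best epoch stays 1
        cfg = TftConfig(hidden_size=8, attention_heads=2, encoder_length=24,
                        max_epochs=50, early_stop_patience=4, batch_size=64,
                        learning_rate=0.0, seed=1)
        f = fit_tft(w.train, w.validation, config=cfg)
        assert f.epochs_run == 1 + cfg.early_stop_patience

    def test_forecasts_finite_and_multivariate_aligned(self, default_pair):
        inc, une = default_pair
        w = make_windows(inc)[0]
        uw = _pair_window(w, une)
        f = fit_tft((w.train, uw.train), w.validation, config=self.SMALL)
        extend_history(f, [w.history, uw.history])
        r = f.predict(24)
        assert r.forecast.shape == (24,)
        assert np.all(np.isfinite(r.forecast))
        assert r.extra_targets["unemployment"].shape == (24,)

    def test_multivariate_learns_lagged_unemployment_driver(self):
        """Incidence driven purely by lagged persistent unemployment: the
        joint model conditions on the observed unemployment state and beats
        the univariate model on the test horizon."""
        wins = 0
        for seed in (11, 12, 13):
            spec = ScenarioSpec(label="toy", years=10, seed=seed, noise_sd=0.0,
                                ar_coef=0.0, trend=0.0, coupling=(2.0, 0.0),
                                u_ar_coef=0.95, u_noise_sd=0.4)
            inc, une = generate_group(spec)
            w = make_windows(inc)[0]
            uw = _pair_window(w, une)
            cfg = TftConfig(hidden_size=8, attention_heads=2, encoder_length=24,
                            max_epochs=100, early_stop_patience=15,
                            batch_size=64, seed=99)
            fu = fit_tft(w.train, w.validation, config=cfg)
            fm = fit_tft((w.train, uw.train), w.validation, config=cfg)
            extend_history(fm, [w.history, uw.history])
            su = smape(w.test.values, fu.predict(24).forecast)
            sm = smape(w.test.values, fm.predict(24).forecast)
            wins += sm < su
        assert wins >= 2

    def test_random_search_returns_best_validation_trial(self, default_pair):
        inc, _ = default_pair
        w = make_windows(inc)[0]
        f = fit_tft(w.train, w.validation, config=self.SMALL, n_trials=2, seed=3)
        assert np.isfinite(f.validation_smape)
        assert f.config.hidden_size in (8, 16, 32)
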