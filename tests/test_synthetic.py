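"""Generator contracts: determinism, event injection, standardization."""

import numpy as np
import pytest

from breakcast.synthetic import (DEFAULT_REFERENCE_WEIGHTS, BreakEvent,
                                 ScenarioSpec, default_panel_specs,
                                 generate_group, generate_panel, group_seed)


def _spec(**kw):
    base = dict(label="g", years=10, seed=1)
    base.update(kw)
    return ScenarioSpec(**base)


def test_identical_spec_bitwise_identical_series():
    a, ua = generate_group(_spec())
    b, ub = generate_group(_spec())
    np.testing.assert_array_equal(a.values, b.values)
    np.testing.assert_array_equal(ua.values, ub.values)


def test_noise_free_series_is_exactly_periodic():
    inc, _ = generate_group(_spec(noise_sd=0, u_noise_sd=0, ar_coef=0,
                                  coupling=(0, 0), trend=0.0))
    v = inc.values
    np.testing.assert_allclose(v[:12], v[12:24], rtol=0, atol=1e-12)
    spec = _spec(noise_sd=0, u_noise_sd=0, ar_coef=0, coupling=(0, 0), trend=0.0)
    np.testing.assert_allclose(v[:12], spec.baseline + spec.seasonal, atol=1e-12)


def test_noise_free_level_shift_is_exact_step():
    m, S = 60, 3.0
    ev = BreakEvent("level_shift", onset=m, magnitude=S)
    inc, _ = generate_group(_spec(noise_sd=0, u_noise_sd=0, ar_coef=0,
                                  coupling=(0, 0), trend=0.0, events=(ev,)))
    # compare same calendar months before/after so seasonality cancels
    assert inc.values[m : m + 12].mean() - inc.values[m - 12 : m].mean() == pytest.approx(S)


def test_event_magnitude_recoverable_against_counterfactual():
    events = (BreakEvent("sharp_interruption", onset=24, magnitude=2.5, duration=6),
              BreakEvent("level_shift", onset=60, magnitude=-1.0))
    spec = _spec(events=events)
    with_ev, _ = generate_group(spec)
    without, _ = generate_group(spec.without_events())
    diff = with_ev.values - without.values
    expected = sum(ev.profile(spec.n_months) for ev in events)
    np.testing.assert_allclose(diff, expected, atol=1e-12)


def test_monte_carlo_level_shift_recovery():
    """Post/pre 12-month mean difference is an unbiased estimate of the
    injected step, with spread matching the AR(1)-adjusted standard error."""
    S, sigma, phi = 1.5, 0.5, 0.3   # 3-sigma step on the default noise
    # independent oracle: SE of the difference of two 12-month means of an
    # AR(1) process, var = 2 * (sigma^2/(1-phi^2))/12 * [1 + 2 sum (1-k/12) phi^k]
    var_x = sigma ** 2 / (1 - phi ** 2)
    factor = 1 + 2 * sum((1 - k / 12) * phi ** k for k in range(1, 12))
    se_diff = np.sqrt(2 * var_x * factor / 12)
    diffs = []
    for i in range(200):
        ev = BreakEvent("level_shift", onset=60, magnitude=S)
        inc, _ = generate_group(_spec(seed=5000 + i, trend=0.0,
                                      coupling=(0, 0), events=(ev,)))
        diffs.append(inc.values[60:72].mean() - inc.values[48:60].mean())
    diffs = np.asarray(diffs)
    assert abs(diffs.mean() - S) < 3 * se_diff / np.sqrt(200)
    within = np.mean(np.abs(diffs - S) <= 2 * se_diff)
    assert within >= 0.90   # nominal ~95%, binomial slack at n=200


def test_incidence_invariant_to_unemployment_spec_when_uncoupled():
    a, _ = generate_group(_spec(coupling=(0, 0)))
    b, _ = generate_group(_spec(coupling=(0, 0), u_baseline=9.0, u_ar_coef=0.5))
    np.testing.assert_array_equal(a.values, b.values)


def test_invalid_specs_rejected():
    with pytest.raises(ValueError, match="sum to zero"):
        _spec(seasonal=np.ones(12))
    with pytest.raises(ValueError, match=r"\|phi\| < 1"):
        _spec(ar_coef=1.0)
    with pytest.raises(ValueError, match="outside"):
        _spec(events=(BreakEvent("level_shift", onset=500, magnitude=1.0),))
    with pytest.raises(ValueError, match="duration"):
        BreakEvent("sharp_interruption", onset=0, magnitude=1.0)
    with pytest.raises(ValueError, match="non-stationary"):
        _spec(coupling=(2.0, 1.0))


class TestDirectStandardization:
    def test_identical_groups_give_identical_overall(self):
        specs = [_spec(label=lab, seed=7) for lab in ("a", "b")]
        panel = generate_panel(specs, {"a": 0.4, "b": 0.6})
        np.testing.assert_allclose(panel.incidence_by_label("overall").values,
                                   panel.incidence_by_label("a").values)

    def test_degenerate_weight_selects_single_group(self):
        specs = [_spec(label="a", seed=1), _spec(label="b", seed=2)]
        panel = generate_panel(specs, {"a": 1.0, "b": 0.0})
        np.testing.assert_allclose(panel.incidence_by_label("overall").values,
                                   panel.incidence_by_label("a").values)

    def test_equal_weights_average_constant_groups(self):
        specs = [
            _spec(label="a", baseline=10.0, trend=0, noise_sd=0, u_noise_sd=0,
                  ar_coef=0, coupling=(0, 0), seasonal=np.zeros(12)),
            _spec(label="b", baseline=20.0, trend=0, noise_sd=0, u_noise_sd=0,
                  ar_coef=0, coupling=(0, 0), seasonal=np.zeros(12)),
        ]
        panel = generate_panel(specs, {"a": 0.5, "b": 0.5})
        np.testing.assert_allclose(panel.incidence_by_label("overall").values, 15.0)

    def test_weight_label_mismatch_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            generate_panel([_spec(label="a")], {"b": 1.0})


def test_group_seed_stable_under_added_groups():
    specs5 = default_panel_specs(42)
    inc5 = {s.label: generate_group(s)[0].values for s in specs5}
    assert group_seed(42, "20-29") == specs5[0].seed
    # regenerating any single group alone gives the same stream
    solo, _ = generate_group(specs5[2])
    np.testing.assert_array_equal(solo.values, inc5[specs5[2].label])
    assert set(DEFAULT_REFERENCE_WEIGHTS) == {s.label for s in specs5}
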