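"""SMAPE properties, score tables and paired comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from breakcast.evaluation import (ScoreTable, compare_models, scenario_report,
                                  score_windows, smape)
from breakcast.synthetic import ScenarioSpec, generate_group
from breakcast.windowing import label_windows, make_windows


class TestSmape:
    def test_zero_on_identical_series(self):
        assert smape([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_checked_example(self):
        # (100/2) * (10/105 + 10/95) = 10.0250...
        assert smape([100, 100], [110, 90]) == pytest.approx(10.0251, abs=1e-3)

    def test_symmetric_in_arguments(self):
        a, f = [3.0, 5.0, 8.0], [4.0, 4.5, 9.0]
        assert smape(a, f) == smape(f, a)

    def test_all_zero_one_side_gives_200(self):
        assert smape([0.0, 0.0], [1.0, 5.0]) == pytest.approx(200.0)

    def test_both_zero_contributes_nothing(self):
        assert smape([0.0, 10.0], [0.0, 10.0]) == 0.0

    @settings(max_examples=100, deadline=None)
    @given(arrays(float, 8, elements=st.floats(0, 1e6)),
           arrays(float, 8, elements=st.floats(0, 1e6)))
    def test_bounds_for_nonnegative_series(self, a, f):
        v = smape(a, f)
        assert 0.0 <= v <= 200.0

    def test_contract_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            smape([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="empty"):
            smape([], [])


def _toy_windows():
    inc, _ = generate_group(ScenarioSpec(label="g", years=12, seed=5))
    return label_windows(make_windows(inc))


class TestScoreWindows:
    def test_perfect_forecast_scores_zero(self):
        wins = _toy_windows()[:1]
        w = wins[0]
        table = score_windows(wins, {(w.group, w.start_year, "m"): w.test.values})
        assert table.rows["test_smape"].iloc[0] == 0.0

    def test_aggregates_are_hand_means(self):
        wins = _toy_windows()[:3]
        results = {}
        scores = [2.0, 4.0, 9.0]
        for w, s in zip(wins, scores):
            f = w.test.values * (1 + s / 100.0)  # roughly s% off, recompute below
            results[(w.group, w.start_year, "m")] = f
        table = score_windows(wins, results)
        expected = table.rows["test_smape"].mean()
        agg = table.aggregates()
        by_class = agg.groupby("stability")["mean_smape"].mean()
        got = (table.rows.groupby("stability")["test_smape"].mean())
        pd.testing.assert_series_equal(by_class, got, check_names=False)
        assert expected == pytest.approx(table.rows["test_smape"].mean())

    def test_scoring_ignores_validation_values(self):
        wins = _toy_windows()[:1]
        w = wins[0]
        results = {(w.group, w.start_year, "m"): w.test.values + 1.0}
        t1 = score_windows(wins, results)
        mutated = w.series.with_values(
            np.r_[w.series.values[:84], w.series.values[84:96] + 50,
                  w.series.values[96:]])
        from dataclasses import replace
        w2 = replace(w, series=mutated)
        t2 = score_windows([w2], results)
        assert (t1.rows["test_smape"].iloc[0]
                == t2.rows["test_smape"].iloc[0])

    def test_duplicate_model_rows_rejected(self):
        rows = pd.DataFrame({
            "group": ["g", "g"], "start_year": [2002, 2002],
            "stability": ["stable"] * 2, "scenario": ["none"] * 2,
            "model": ["m", "m"], "test_smape": [1.0, 2.0],
        })
        with pytest.raises(ValueError, match="duplicate"):
            ScoreTable(rows)


def _table(a_scores, b_scores, stability="stable"):
    rows = []
    for i, (a, b) in enumerate(zip(a_scores, b_scores)):
        rows.append(dict(group="g", start_year=2000 + i, stability=stability,
                         scenario="none", model="A", test_smape=a))
        rows.append(dict(group="g", start_year=2000 + i, stability=stability,
                         scenario="none", model="B", test_smape=b))
    return ScoreTable(pd.DataFrame(rows))


class TestCompareModels:
    def test_matches_scipy_paired_t(self):
        a, b = [10.0, 12.0, 11.0, 14.0], [13.0, 15.0, 13.0, 14.5]
        c = compare_models(_table(a, b), "A", "B", "stable")
        t_ref, p_ref = stats.ttest_rel(a, b)
        assert c.t == pytest.approx(t_ref)
        assert c.p == pytest.approx(p_ref)
        assert c.mean_diff == pytest.approx(np.mean(np.array(a) - np.array(b)))

    def test_identical_vectors_give_p_one(self):
        c = compare_models(_table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]), "A", "B")
        assert c.p == 1.0 and c.mean_diff == 0.0

    def test_constant_offset_zero_variance_flagged(self):
        c = compare_models(_table([3.0, 5.0, 7.0], [1.0, 3.0, 5.0]), "A", "B")
        assert c.flag == "zero-variance"
        assert c.p == 0.0 and c.mean_diff == pytest.approx(2.0)

    def test_antisymmetric_in_model_order(self):
        t = _table([10.0, 12.0, 11.0], [13.0, 10.0, 14.0])
        ab = compare_models(t, "A", "B")
        ba = compare_models(t, "B", "A")
        assert ab.p == pytest.approx(ba.p)
        assert ab.mean_diff == pytest.approx(-ba.mean_diff)

    def test_insufficient_windows_is_error(self):
        with pytest.raises(ValueError, match="insufficient"):
            compare_models(_table([1.0, 2.0], [2.0, 3.0]), "A", "B")


class TestScenarioReport:
    def test_argmin_flagged_and_ties_joint(self):
        rows = []
        for model, s in [("arima", 12.0), ("varima", 12.0), ("unitft", 15.0)]:
            rows.append(dict(group="g", start_year=2002, stability="unstable",
                             scenario="level_shift", model=model, test_smape=s))
        rep = scenario_report(ScoreTable(pd.DataFrame(rows)))
        assert rep.loc[0, "best"] == "arima,varima"
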