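# breakcast

Forecast-model comparison for monthly disease-incidence series under
structural breaks.

Population-wide incidence of depression — and of many other conditions shaped
by socioeconomic stressors — does not evolve smoothly: pandemics, economic
crises and social unrest interrupt the series with transient surges ("sharp
interruptions") or persistent jumps ("level shifts").  Which forecasting
model to trust depends on which of these regimes the forecast period falls
into.  `breakcast` is a reusable, tested pipeline for answering that question
on monthly panels of incidence (per 100,000 per month) coupled with
unemployment rates (%):

1. **Synthetic panels** — a generator for coupled incidence/unemployment
   series per age group with trend, annual seasonality, AR(1) noise, a
   bidirectional cross-lag between the two outcomes, injectable break events,
   and direct age standardization of an "overall" series with fixed reference
   weights.  It stands in for access-restricted patient registries.
2. **Structural breaks** — the Chow test at every adjacent-year junction:
   with residual sums of squares from separate and pooled OLS fits
   (intercept + month index, k = 2),
   `F = [(RSS_p − RSS_A − RSS_B)/k] / [(RSS_A + RSS_B)/(n_A + n_B − 2k)]`
   referred to F(k, 20); rejected junctions are then classified as sharp
   interruption (series returns to the pre-break level within a 12-month
   horizon) or level shift (it stays away).
3. **Sliding windows** — 10-year subsamples slid year by year: 7 years
   training, 1 year validation, 2 years test (84/12/24 months), labelled
   *stable* when none of the year 7–8, 8–9, 9–10 junctions rejects.
4. **Four forecasters behind one contract** — ARIMA(p,1,q), bivariate
   VARIMA, and univariate/multivariate temporal fusion transformers (TFT)
   implemented in NumPy with an in-house reverse-mode autodiff core, trained
   with a SMAPE loss, dropout, gradient clipping, Adam, reduce-on-plateau
   scheduling and early stopping.
5. **Evaluation** — symmetric mean absolute percentage error on the 24-month
   test segment, `SMAPE = (100/n) Σ |F_t−A_t| / ((|A_t|+|F_t|)/2)` (0–200%),
   aggregated per stability class and compared across models by paired
   t tests, plus per-scenario best-model tables.

## Worked example

Score all four models on one synthetic 10-year window whose validation year
contains a 12-month pandemic-scale surge that subsides midway through the
test years (the "sharp interruption" archetype):

```python
from breakcast.studies import run_scenario_seed, scenario_window

window = scenario_window("sharp", seed=11)
w, _ = window
print("window:", w.group, w.start_year, w.stability, w.scenario)
for model, s in run_scenario_seed("sharp", 11, window=window).items():
    print(f"{model:>9}: test SMAPE {s:5.1f}%")
```

prints

```
window: sharp 2002 unstable level_shift
    arima: test SMAPE  25.2%
   varima: test SMAPE  29.5%
   unitft: test SMAPE  13.1%
 multitft: test SMAPE  13.2%
```

The integrated linear models anchor their forecasts on the still-elevated
last observed months and overshoot once the surge subsides (SMAPE ≈ 25–30%),
while the attention-based models keep projecting the seasonal/trend pattern
learned from seven undisturbed training years and recover quickly
(SMAPE ≈ 13%).  On persistent level shifts the ordering reverses: first-order
differencing lets ARIMA/VARIMA re-anchor on the new level, whereas the TFTs
keep predicting the old one.

The same comparison over many seeded windows, stratified by scenario:

```python
from breakcast.studies import run_directional_study, class_medians
study = run_directional_study(n_seeds=20, master_seed=0)
print(class_medians(study, "sharp"))   # median SMAPE per model class
```

## Command line

```bash
breakcast simulate --seed 1 --years 21 --out panel/
breakcast breaks   --incidence panel/incidence.csv --alpha 0.05 --out breaks.csv
breakcast windows  --incidence panel/incidence.csv --out windows.csv
breakcast run      --demo --seed 1 --out results/
```

Stages read and write plain CSV (`month,<group>,...` with ISO `YYYY-MM`
months), so each is independently runnable; `run` composes them and writes
the window inventory, score table, paired comparisons, scenario report and a
manifest with the config hash and master seed.

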