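# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices and the known limitations of `breakcast`.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic data-generating process

Monthly incidence registries at population scale are access-restricted, so
the package runs on synthetic panels built to exhibit exactly the features
the analysis exploits: trend, annual seasonality, autocorrelated noise,
bidirectional incidence–unemployment coupling, and abrupt breaks of two
archetypes.  For one group,

```
I_t = mu + beta t + s_{month(t)} + e_t + event_t        (per 100,000/month)
U_t = mu_U + beta_U t + f_t                              (percent)

e_t = phi_I e_{t-1} + b_IU f_{t-1} + eps_t,   eps_t ~ N(0, sigma_I^2)
f_t = phi_U f_{t-1} + b_UI e_{t-1} + eta_t,   eta_t ~ N(0, sigma_U^2)
```

Defaults (per-group overrides for the five age bands shift the levels):
`mu = 10` per 100,000 per month with a gentle trend `beta = 0.01`/month —
the scale of adult depression-incidence series; seasonal profile a zero-sum
cosine of amplitude 0.8 (winter peak); `sigma_I = 0.5`, `phi_I = 0.3`
(mild month-to-month persistence in the deviations); unemployment around 4%
with `phi_U = 0.9`, `sigma_U = 0.15` (unemployment moves slowly); default
coupling `(b_IU, b_UI) = (0.15, 0.02)` on mean-centred deviations, with the
spectral radius of the implied VAR(1) matrix validated < 1.

Break events are **added to the incidence output after the recursion**, not
fed back through it.  This makes every injected event exactly recoverable by
differencing against the no-event counterfactual, at the cost of not
propagating shocks into unemployment — a deliberate trade of realism for
testability.  Negative incidence is clipped at zero and the clipping logged,
because it breaks additivity.

Each group draws from an RNG stream keyed by (master seed, group label), so
adding or reordering groups never perturbs existing groups.  The "overall"
series is the direct standardization `I_std,t = Σ_a w_a I_a,t` with fixed
reference weights (a plausible adult age distribution; synthetic stand-in
for a census reference year).

What the generator does **not** emulate: reporting artefacts and
registry-coverage drift, demographic change over time, count noise at small
denominators (values are Gaussian around the mean, not Poisson), and shocks
that enter through unemployment.  Passing tests therefore demonstrate the
pipeline's behaviour under a clean additive regime, not performance on real
registry data.

## Seasonal adjustment and stationarity

Classical additive decomposition: trend = centred 2×12 moving average,
seasonal effect = mean monthly deviation from it, recentred to sum to zero;
residual is the remainder.  Classical (not STL) because the downstream
models only need a fixed monthly profile, and the profile is always
estimated from the **training segment only** and applied to later months by
calendar-month lookup — no leakage, asserted in tests.

ARIMA/VARIMA receive deseasonalized series and their forecasts are
reseasonalized; the TFT variants receive raw series plus calendar-month
dummies as known-future covariates.  Rationale: linear models have no native
categorical handling, while the TFT's variable-selection stage is built for
covariates.  Deseasonalization happens before differencing.

ADF and KPSS (via statsmodels) determine the order of integration d as the
smallest d ∈ {0,1,2} where ADF rejects its unit root and KPSS does not
reject stationarity, with zero-variance and inconclusive flags for the
degenerate cases.  The pipeline nevertheless fixes d = 1 for both outcomes —
monthly incidence and unemployment behave as I(1) — and keeps the verdict
for audit.

## Chow test and scenario taxonomy

Each adjacent-year junction (12 + 12 points) is tested by the Chow F
statistic on OLS fits with intercept and global month index (k = 2; a
constant-only k = 1 variant is available), so both intercept and slope
changes count as breaks.  α defaults to 0.05 and no multiple-testing
correction is applied across junctions — per-junction decisions are reported
raw, which is the convention this pipeline mirrors.  Degenerate noise-free
cases are closed off exactly: all-zero RSS ⇒ F = 0 (one coherent line);
zero within-segment RSS with pooled misfit ⇒ p = 0.

Two calibration facts, both computed in the tests:

- the test is exact only under serially independent errors: with AR(1)
  persistence φ = 0.3 in the noise the empirical size at α = 0.05 is ≈ 0.17;
- unmodelled seasonality inflates the within-segment RSS and makes the test
  *conservative* (size ≈ 0.004 under the default seasonal amplitude).

The calibration check therefore runs under the test's own null model
(intercept + trend + iid Gaussian noise), where the measured size falls
inside the 99% binomial envelope of α.

A rejected junction at month m is classified by where the series settles:
with `pre` = mean of the 12 months before m and `post_far` = mean of months
m+12 … m+23, the label is *sharp interruption* if |post_far − pre| ≤ 1 ×
SD of the pre-break residuals (about a linear fit of the pre year), else
*level shift*; fewer than 6 settled months ⇒ *indeterminate*.  Horizon and
tolerance are configurable.  Two caveats, measured in the validation
studies: a deterministic trend biases the level comparison (the 24-month
drift is absorbed into the difference), and persistent coupled noise widens
it; the break-recovery study therefore runs on the trendless, uncoupled
generator variant, where 4σ events are detected and correctly classified in
≥ 90% of 200 replicates.  The junction between years 9 and 10 of a 10-year
window can never be classified within the window (no settled data follows).

## Windows and stability labels

Windows are calendar-aligned 10-year slices stepped one year at a time:
84 months train, 12 validation, 24 test.  A 21-year span yields 12 windows
per group; five age bands plus the standardized overall series give 72.
Only the three late junctions (years 7–8, 8–9, 9–10) decide stability —
a break wholly inside the training years does not make validation/test a
non-smooth extension of training.  When several rejected junctions disagree,
the window's scenario is the earliest rejected junction's label (the first
shock dominates the test period); a "latest" rule is available.

## Forecasters

All four models share one contract: fit on the 84 training months, select
hyperparameters/orders by SMAPE on the 12 validation months, then emit 24
monthly point forecasts on the original scale conditioned on the
train+validation history.  Model selection never touches the test segment.

**ARIMA** — statsmodels ARIMA(p, 1, q) with trend "n" (no drift) or "c"
(constant drift); p ∈ 0..3, q ∈ 0..2 (24 configurations).  Ties prefer
smaller p+q, then "n".  Parameters are estimated on the training segment
only; test forecasts apply those parameters to the train+validation history
(`ARIMAResults.apply`).  Non-convergent configurations are skipped with a
log entry.

**VARIMA** — statsmodels VARMAX(p, q) on the first-differenced
deseasonalized (incidence, unemployment) pair, same grid and selection;
difference forecasts are integrated back from the last observed
pre-forecast level and reseasonalized.  Both outcomes are forecast jointly;
incidence is scored.

**TFT** — a compact temporal fusion transformer on an in-house NumPy
reverse-mode autodiff core (no GPU framework dependency): per-variable
linear/embedding input transforms; variable-selection weights from a gated
residual network (GRN: ELU bottleneck, GLU gate, residual + layer norm);
LSTM encoder over `encoder_length` past months and LSTM decoder over the
forecast months; gated skip connections; static enrichment from a
target-identity embedding; interpretable multi-head attention (per-head
queries/keys, shared values, averaged heads) over the full sequence with a
causal mask; a position-wise GRN; and a linear point-forecast head.
Training minimizes SMAPE on the original scale (denominator floored at
ε = 10⁻³ for gradient stability; the A = F = 0 term is 0 by continuous
extension) with dropout, global-norm gradient clipping, Adam,
reduce-on-plateau decay (factor 0.5 after patience/3 flat epochs) and early
stopping that halts exactly `patience` epochs after the best validation
SMAPE.  Fixed seed and config give bit-identical runs.  Hyperparameter
search is a seeded random search over hidden ∈ {8,16,32}, heads ∈ {1,2,4},
dropout ∈ [0.1,0.3], lr ∈ [10⁻³,10⁻²] (log-uniform), batch ∈ {16,32,64} —
the smallest space that trains in minutes on one CPU core for an 84-month
series.

The **multivariate TFT** is one shared network: both series enter as past
inputs, a target-ID embedding selects the emitted series, and two additions
make the cross-series information usable at this data scale (84 training
months, ~50 samples):

- the forecast-origin level of each auxiliary target (the latest observed
  unemployment, a known quantity at forecast time) is a known decoder
  input, giving the decoder a direct conditioning path to the socioeconomic
  state instead of requiring it to be carried through the LSTM bottleneck;
- per-target loss weights (ratio of the primary target's lag-12 naive SMAPE
  to the auxiliary's, computed on training data) stop unemployment's larger
  relative errors from dominating the shared gradients.

Without these, a diagnostic in the test suite (incidence driven purely by
lagged persistent unemployment) shows the joint model cannot beat the
univariate one even when the cross-signal is the only signal.  No incidence
anchor is fed to either variant's decoder: the TFTs remain pattern-based
with respect to their own recent level, which is precisely the mechanism
behind their robustness to transient surges.

VARIMA's back-integration from the last observed level, and estimating on
train only while conditioning test forecasts on train+validation, are
deliberate conventions (the alternatives — refitting on train+validation,
or anchoring on the last training level — are a one-line change).

## Evaluation

SMAPE in the mean-of-ratios form with half-sum denominator (range 0–200%),
the definition used by the common TFT training stacks; stated prominently
because variants abound.  Model comparisons are two-sided **paired** t tests
on per-window SMAPE differences — all models score the same windows, so
pairing is the appropriate design; an unpaired variant is a flag away.
Zero-variance differences are closed off: identical vectors ⇒ p = 1,
constant nonzero offset ⇒ p = 0 with a flag.  Aggregates weight each window
equally.  No correction across model pairs; p-values are raw.

## Scenario studies and problem sizes

`breakcast.studies` fixes three 10-year single-window archetypes:

- **sharp** — a +4 per 100,000 pulse (≈ 8 noise SDs, a pandemic-scale
  shock) for 12 months starting in July of the validation year, so the
  surge covers the forecast origin and subsides mid-test;
- **shift** — a +4 per 100,000 step from January of the validation year;
- **stable** — no events, strong coupling (b_IU = 1.5, φ_U = 0.92,
  σ_U = 0.35: the coupled component's SD is ~2.7× the intrinsic innovation
  SD), keeping only windows the Chow screen labels stable, as real windows
  would be stratified.

Study fits use a compact TFT (hidden 8, 2 heads, encoder 24, ≤ 100 epochs,
patience 15, batch 64) and a reduced VARIMA grid (p, q ≤ 1); these sizes
are chosen so a 20-seed, 3-scenario, 4-model study completes in minutes on
one CPU core.  The qualitative orderings — TFT classes more accurate on
sharp interruptions, linear models on level shifts — are large (median gaps
of ~8 and ~25 SMAPE points) and stable across seeds.  The stable-scenario
multivariate-vs-univariate TFT comparison is a genuinely small effect:
median gaps of ~0.2–1.5 SMAPE points against a seed-to-seed spread several
times larger, so its direction can flip between master seeds even at 20
windows.  It holds under the frozen study seed, and the acceptance script
reports whatever the requested seed produces.

## Known limitations

- The Chow screen tests fixed year boundaries only; no unknown-breakpoint
  search (sup-F / multiple-break estimation) is attempted.
- Order selection by 12-month validation SMAPE is a forecast-skill
  criterion, not an identification procedure: it reliably rejects the naive
  model on persistent series but does not recover exact ARMA orders.
- Point forecasts only; no probabilistic head.
- The TFT is deliberately small; it is sized for 84-month training series,
  not for long or high-frequency data.
- Incidence clipping at zero breaks additivity in extreme scenarios (logged
  when it happens).
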