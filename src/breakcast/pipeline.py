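"""Config-driven orchestration of the full windowed model comparison.

One experiment = generate (or load) a monthly incidence/unemployment panel,
cut each group's series into sliding 10-year windows, label window stability
with the Chow test, fit the requested forecasters on every window, score the
24-month test segments by SMAPE, and write the window inventory, score table,
pairwise comparisons and scenario report to an output directory together with
a manifest recording the config hash and master seed.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .evaluation import compare_models, scenario_report, score_windows
from .forecasters import (TftConfig, default_arima_grid, extend_history,
                          fit_arima, fit_tft, fit_varima)
from .series import MonthlySeries, read_series, write_series
from .synthetic import (DEFAULT_REFERENCE_WEIGHTS, default_panel_specs,
                        generate_panel)
from .windowing import (WindowSample, label_windows, make_windows,
                        windows_to_frame)

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_window", "run_experiment"]

MODEL_NAMES = ("arima", "varima", "unitft", "multitft")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one run needs; deterministic given ``seed``."""

    seed: int = 0
    years: int = 21
    alpha: float = 0.05
    window_years: int = 10
    step_years: int = 1
    train_years: int = 7
    val_years: int = 1
    test_years: int = 2
    models: tuple[str, ...] = MODEL_NAMES
    arima_p_max: int = 3
    arima_q_max: int = 2
    arima_trends: tuple[str, ...] = ("n", "c")
    varima_p_max: int = 1
    varima_q_max: int = 1
    tft_trials: int = 1
    tft_config: TftConfig = field(default_factory=TftConfig)
    out_dir: str = "breakcast_out"
    # panel source: synthetic by default, or CSV paths for both variables
    csv_incidence: str | None = None
    csv_unemployment: str | None = None

    def __post_init__(self) -> None:
        if self.train_years + self.val_years + self.test_years != self.window_years:
            raise ValueError(
                f"split {self.train_years}+{self.val_years}+{self.test_years} "
                f"does not sum to window of {self.window_years} years"
            )
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown models {sorted(unknown)}")
        for path in (self.csv_incidence, self.csv_unemployment):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def window_seed(master_seed: int, group: str, start_year: int, model: str) -> int:
    """Deterministic per-(group, window, model) seed for partial reruns."""
    return int(np.random.SeedSequence([
        int(master_seed) & 0x7FFFFFFF,
        zlib.crc32(group.encode()),
        int(start_year),
        zlib.crc32(model.encode()),
    ]).generate_state(1)[0] & 0x7FFFFFFF)


def _pair_window(window: WindowSample, unemployment: MonthlySeries) -> WindowSample:
    """The matching 10-year unemployment window for an incidence window."""
    offset = (window.series.start - unemployment.start).n
    return WindowSample(
        group=window.group, start_year=window.start_year,
        series=unemployment.slice(offset, len(window.series)),
    )


def run_window(
    window: WindowSample,
    unemployment: MonthlySeries,
    config: ExperimentConfig,
) -> dict[str, np.ndarray]:
    """Fit every requested model on one window; 24-month test forecasts."""
    une_w = _pair_window(window, unemployment)
    horizon = len(window.test)
    arima_grid = default_arima_grid(config.arima_p_max, config.arima_q_max,
                                   config.arima_trends)
    varima_grid = default_arima_grid(config.varima_p_max, config.varima_q_max,
                                    config.arima_trends)
    out: dict[str, np.ndarray] = {}
    for model in config.models:
        seed = window_seed(config.seed, window.group, window.start_year, model)
        t0 = time.perf_counter()
        if model == "arima":
            fitted = fit_arima(window.train, window.validation, grid=arima_grid)
        elif model == "varima":
            fitted = fit_varima((window.train, une_w.train),
                                (window.validation, une_w.validation),
                                grid=varima_grid)
        elif model == "unitft":
            fitted = fit_tft(window.train, window.validation,
                             config=replace(config.tft_config, seed=seed),
                             n_trials=config.tft_trials, seed=seed)
        else:  # multitft
            fitted = fit_tft((window.train, une_w.train), window.validation,
                             config=replace(config.tft_config, seed=seed),
                             n_trials=config.tft_trials, seed=seed)
            extend_history(fitted, [window.history, une_w.history])
        result = fitted.predict(horizon)
        logger.info("stage=forecast group=%s start=%d model=%s wall=%.2fs",
                    window.group, window.start_year, model,
                    time.perf_counter() - t0)
        out[model] = result.forecast
    return out


def _load_panel(config: ExperimentConfig) -> tuple[list[MonthlySeries], dict[str, MonthlySeries]]:
    if config.csv_incidence is not None:
        if config.csv_unemployment is None:
            raise ValueError("csv_unemployment required with csv_incidence")
        incidence = read_series(config.csv_incidence, units="per 100,000")
        unemployment = read_series(config.csv_unemployment, units="percent")
    else:
        specs = default_panel_specs(config.seed, years=config.years)
        panel = generate_panel(specs, DEFAULT_REFERENCE_WEIGHTS)
        incidence = list(panel.incidence)
        unemployment = list(panel.unemployment)
    une_by_label = {s.label: s for s in unemployment}
    missing = [s.label for s in incidence if s.label not in une_by_label]
    if missing:
        raise ValueError(f"no unemployment series for groups {missing}")
    return incidence, une_by_label


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full comparison; returns the artifact bundle in memory too."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    incidence, une_by_label = _load_panel(config)

    all_windows: list[WindowSample] = []
    for series in incidence:
        wins = make_windows(series, config.window_years, config.step_years)
        all_windows.extend(label_windows(wins, alpha=config.alpha))

    results, failures = {}, []
    for w in all_windows:
        try:
            forecasts = run_window(w, une_by_label[w.group], config)
        except Exception as exc:
            failures.append({"group": w.group, "start_year": w.start_year,
                             "error": str(exc)})
            logger.warning("window (%s, %d) failed: %s", w.group, w.start_year, exc)
            continue
        for model, fc in forecasts.items():
            results[(w.group, w.start_year, model)] = fc

    table = score_windows([w for w in all_windows
                           if any(k[0] == w.group and k[1] == w.start_year
                                  for k in results)], results)

    comparisons = []
    for stratum in ("stable", "unstable"):
        present = table.rows[table.rows["stability"] == stratum]
        models = sorted(present["model"].unique())
        for a, b in itertools.combinations(models, 2):
            try:
                c = compare_models(table, a, b, stratum)
            except ValueError:
                continue
            comparisons.append(vars(c))

    inventory = windows_to_frame(all_windows)
    report = scenario_report(table)
    aggregates = table.aggregates()

    inventory.to_csv(out_dir / "windows.csv", index=False)
    table.rows.to_csv(out_dir / "scores.csv", index=False)
    aggregates.to_csv(out_dir / "aggregates.csv", index=False)
    report.to_csv(out_dir / "scenario_report.csv", index=False)
    import pandas as pd
    pd.DataFrame(comparisons).to_csv(out_dir / "comparisons.csv", index=False)
    write_series(out_dir / "incidence.csv", incidence)
    write_series(out_dir / "unemployment.csv", list(une_by_label.values()))
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_windows": len(all_windows),
        "n_failures": len(failures),
        "failures": failures,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "windows": all_windows,
        "inventory": inventory,
        "scores": table,
        "aggregates": aggregates,
        "comparisons": comparisons,
        "scenario_report": report,
        "failures": failures,
    }
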