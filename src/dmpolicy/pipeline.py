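"""High-level drivers: calibrated scenario runs and publication-style tables."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import (
    ANCHOR_YEARS,
    CalibrationResult,
    calibrate,
    solve_incidence_growth,
)
from .emulator import (
    FAMILY_PREDICTORS,
    LognormalSpec,
    design_runs,
    fit_emulator,
    propagate,
    runs_to_frame,
)
from .model import project
from .scenarios import (
    DEFAULT_POPULATION_EFFECTIVENESS,
    DEFAULT_TARGETED_EFFECTIVENESS,
    SCENARIO_NAMES,
    compare_scenarios,
    make_scenario,
)


def run_scenarios(
    calibration: CalibrationResult,
    names: Sequence[str] = SCENARIO_NAMES,
    targeted_eff: float = DEFAULT_TARGETED_EFFECTIVENESS,
    population_eff: float = DEFAULT_POPULATION_EFFECTIVENESS,
    incidence_growth: float = 1.0,
    end_year: int | None = None,
) -> dict:
    """Project every named scenario on the calibrated model."""
    params = calibration.params.with_(incidence_growth=incidence_growth)
    out = {}
    for name in names:
        scenario = make_scenario(name, targeted_eff, population_eff)
        out[name] = project(
            calibration.initial, params, calibration.demography, scenario, end_year
        )
    return out


def projection_2030_count(calibration: CalibrationResult, incidence_growth: float = 1.0):
    """Callable mapping a scenario to its 2030 prevalent diabetes count."""
    params = calibration.params.with_(incidence_growth=incidence_growth)

    def run(scenario) -> float:
        res = project(calibration.initial, params, calibration.demography, scenario)
        return float(res.diabetes_count[-1])

    return run


def scenario_table(results: dict, anchor_years: np.ndarray = ANCHOR_YEARS) -> pd.DataFrame:
    """Per-scenario projections at the anchor years plus comparison metrics.

    Mirrors the published layout: cumulative incidence, prevalence count and
    prevalence rate per anchor year, the 2007-2030 change, and the relative
    attenuation of that change versus no intervention.
    """
    comparison = compare_scenarios(results).set_index("scenario")
    rows = []
    for name, res in results.items():
        row: dict = {"scenario": name}
        for year in anchor_years:
            sv = res.at(int(year))
            row[f"cumulative_incidence_{year}"] = res.cumulative_incidence_at(int(year))
            row[f"prevalence_millions_{year}"] = sv.diabetes_count
            row[f"prevalence_rate_pct_{year}"] = 100.0 * sv.prevalence_rate
        row["count_change_2007_2030"] = (
            res.diabetes_count[-1] - res.diabetes_count[0]
        )
        row["rate_change_2007_2030_pp"] = comparison.loc[name, "change_2007_2030_pp"]
        if name != "none":
            row["relative_attenuation_rate_pct"] = comparison.loc[
                name, "relative_attenuation_rate"
            ]
            row["relative_attenuation_count_pct"] = comparison.loc[
                name, "relative_attenuation_count"
            ]
        rows.append(row)
    return pd.DataFrame(rows)


# One-variable-at-a-time sensitivity design: each row changes a single
# base-case assumption.
SENSITIVITY_ROWS = (
    ("base_case", dict()),
    ("increasing_background_incidence", dict(increasing_background=True)),
    ("targeted_effectiveness_25pct", dict(targeted_eff=0.25)),
    ("targeted_effectiveness_6.25pct", dict(targeted_eff=0.0625)),
    ("population_effectiveness_1pct", dict(population_eff=0.01)),
    ("population_effectiveness_4pct", dict(population_eff=0.04)),
)


def sensitivity_table(
    calibration: CalibrationResult,
    rows=SENSITIVITY_ROWS,
    background_rate_increase_pp: float = 3.5,
) -> pd.DataFrame:
    """One-variable-at-a-time sensitivity analysis of prevented 2030 cases.

    Reports, per adjusted assumption and per strategy, the projected
    reduction in 2030 diabetes prevalence versus no intervention, in both
    percentage points of prevalence rate and millions of prevalent cases.
    """
    growth_up = None
    out = []
    for label, changes in rows:
        targeted = changes.get("targeted_eff", DEFAULT_TARGETED_EFFECTIVENESS)
        population = changes.get("population_eff", DEFAULT_POPULATION_EFFECTIVENESS)
        growth = 1.0
        if changes.get("increasing_background"):
            if growth_up is None:
                growth_up = solve_incidence_growth(
                    calibration, background_rate_increase_pp
                )
            growth = growth_up
        results = run_scenarios(
            calibration,
            targeted_eff=targeted,
            population_eff=population,
            incidence_growth=growth,
        )
        base = results["none"]
        row = {
            "assumption": label,
            "targeted_effectiveness": targeted,
            "population_effectiveness": population,
            "incidence_growth": growth,
        }
        for name in ("moderate_risk", "high_risk", "population", "combined"):
            res = results[name]
            row[f"{name}_reduction_pp"] = 100.0 * (
                base.prevalence_rate[-1] - res.prevalence_rate[-1]
            )
            row[f"{name}_reduction_millions"] = (
                base.diabetes_count[-1] - res.diabetes_count[-1]
            )
        out.append(row)
    return pd.DataFrame(out)


def default_effectiveness_grid(base: float, n: int = 5) -> list[float]:
    """Log-spaced effectiveness values spanning half to double the base case."""
    return list(np.exp(np.linspace(np.log(base / 2), np.log(base * 2), n)))


def uncertainty_table(
    calibration: CalibrationResult,
    n_samples: int = 10_000,
    seed: int = 0,
    grid_size: int = 5,
    spread: float = 2.0,
) -> tuple[pd.DataFrame, dict]:
    """Emulator-based approximate 95% credibility intervals per strategy.

    For each scenario family, runs the full model over a log-spaced factorial
    of effectiveness values (half to double the base case per predictor),
    fits the log-linear emulator, and propagates lognormal subjective
    effectiveness distributions (median at the base case, 2.5th/97.5th
    percentiles at half/double).  Returns the summary table and the raw
    runs/fits for reporting.
    """
    model = projection_2030_count(calibration)
    x1_grid = default_effectiveness_grid(DEFAULT_TARGETED_EFFECTIVENESS, grid_size)
    x2_grid = default_effectiveness_grid(DEFAULT_POPULATION_EFFECTIVENESS, grid_size)
    x1_dist = LognormalSpec(DEFAULT_TARGETED_EFFECTIVENESS, spread)
    x2_dist = LognormalSpec(DEFAULT_POPULATION_EFFECTIVENESS, spread)

    rows = []
    artifacts: dict = {}
    for i, family in enumerate(("combined", "population", "high_risk", "moderate_risk")):
        predictors = FAMILY_PREDICTORS[family]
        runs = design_runs(
            family,
            x1_values=x1_grid if "x1" in predictors else (),
            x2_values=x2_grid if "x2" in predictors else (),
            model=model,
        )
        fit = fit_emulator(runs)
        interval = propagate(
            fit,
            x1_distribution=x1_dist if "x1" in predictors else None,
            x2_distribution=x2_dist if "x2" in predictors else None,
            n_samples=n_samples,
            seed=seed + i,
        )
        base_estimate = model(make_scenario("none")) - 0.0
        base_reduction = base_estimate - model(make_scenario(family))
        rows.append(
            {
                "scenario": family,
                "r_squared": fit.r_squared,
                "base_case_reduction_millions": base_reduction,
                "ci_lower_millions": interval.lower,
                "ci_upper_millions": interval.upper,
            }
        )
        artifacts[family] = {"runs": runs_to_frame(runs), "fit": fit}
    return pd.DataFrame(rows), artifacts


def run_all(seed: int = 0, n_samples: int = 10_000):
    """Calibrate and produce every table; convenience for scripts."""
    calibration = calibrate()
    results = run_scenarios(calibration)
    return {
        "calibration": calibration,
        "results": results,
        "scenario_table": scenario_table(results),
        "sensitivity_table": sensitivity_table(calibration),
        "uncertainty": uncertainty_table(calibration, n_samples=n_samples, seed=seed),
    }
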