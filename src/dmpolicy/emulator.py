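"""Log-linear run emulator and error propagation for intervention effects.

A full Monte-Carlo uncertainty assessment over all model inputs is not the
point here: the dominant uncertainty is the effectiveness of hypothetical
interventions, for which no data exist.  The approach is to treat a designed
set of full model runs as a sample, fit an ordinary least-squares emulator

    Y = b0 + b1 ln(X1) + b2 ln(X2) + e

where ``Y`` is the 2030 reduction in prevalent diabetes (millions) versus no
intervention, ``X1`` the targeted-intervention effectiveness and ``X2`` the
population-wide effectiveness, and then push subjective effectiveness
distributions through the fitted emulator (plus its residual noise) to get
approximate 95% credibility intervals, truncated below at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .scenarios import make_scenario

#: Scenario families and which predictors are active for each.
FAMILY_PREDICTORS = {
    "high_risk": ("x1",),
    "moderate_risk": ("x1",),
    "population": ("x2",),
    "combined": ("x1", "x2"),
}


@dataclass(frozen=True)
class EmulatorRun:
    """One full model run of a scenario family at given effectiveness values.

    ``y`` is the reduction in 2030 prevalent diabetes (millions) relative to
    the no-intervention run.  Inactive predictors are stored as NaN.
    """

    x1: float
    x2: float
    y: float


@dataclass(frozen=True)
class EmulatorFit:
    intercept: float
    coef_lnx1: float | None
    coef_lnx2: float | None
    r_squared: float
    residual_sd: float

    def predict(self, x1: float | None = None, x2: float | None = None) -> float:
        y = self.intercept
        if self.coef_lnx1 is not None:
            if x1 is None or x1 <= 0:
                raise ValueError("x1 must be positive for a fit with a ln(x1) term")
            y += self.coef_lnx1 * np.log(x1)
        if self.coef_lnx2 is not None:
            if x2 is None or x2 <= 0:
                raise ValueError("x2 must be positive for a fit with a ln(x2) term")
            y += self.coef_lnx2 * np.log(x2)
        return float(y)


@dataclass(frozen=True)
class CredibilityInterval:
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("interval bounds out of order")


def design_runs(
    scenario_family: str,
    x1_values: Sequence[float] = (),
    x2_values: Sequence[float] = (),
    model: Callable | None = None,
) -> list[EmulatorRun]:
    """Full factorial of model runs over the active effectiveness grids.

    ``model`` maps an :class:`~dmpolicy.scenarios.InterventionScenario` to
    the 2030 prevalent diabetes count (millions); the no-intervention run is
    evaluated once and subtracted from every scenario run.
    """
    if model is None:
        raise ValueError("a projection callable is required")
    predictors = FAMILY_PREDICTORS.get(scenario_family)
    if predictors is None:
        raise ValueError(f"unknown scenario family {scenario_family!r}")
    x1_values = list(x1_values) if "x1" in predictors else []
    x2_values = list(x2_values) if "x2" in predictors else []
    for grid, name in ((x1_values, "x1"), (x2_values, "x2")):
        if grid and (len(set(grid)) < 3 or any(v <= 0 for v in grid)):
            raise ValueError(f"{name} grid needs >= 3 distinct positive values")
        if name in predictors and not grid:
            raise ValueError(f"{name} grid required for family {scenario_family!r}")

    baseline = model(make_scenario("none"))
    runs = []
    grid1 = x1_values or [float("nan")]
    grid2 = x2_values or [float("nan")]
    for x1 in grid1:
        for x2 in grid2:
            scenario = make_scenario(
                scenario_family,
                targeted_eff=0.0 if np.isnan(x1) else x1,
                population_eff=0.0 if np.isnan(x2) else x2,
            )
            runs.append(EmulatorRun(x1=x1, x2=x2, y=baseline - model(scenario)))
    n_predictors = ("x1" in predictors) + ("x2" in predictors)
    if len(runs) < n_predictors + 2:
        raise ValueError("too few runs for a stable fit")
    return runs


def fit_emulator(runs: Sequence[EmulatorRun]) -> EmulatorFit:
    """Ordinary least squares of Y on the log-effectiveness predictors."""
    y = np.array([r.y for r in runs])
    cols = {}
    if not np.isnan(runs[0].x1):
        cols["lnx1"] = np.log([r.x1 for r in runs])
    if not np.isnan(runs[0].x2):
        cols["lnx2"] = np.log([r.x2 for r in runs])
    if not cols:
        raise ValueError("no active predictor in run set")
    X = sm.add_constant(pd.DataFrame(cols), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear or degenerate run design")
    fit = sm.OLS(y, X).fit()
    dof = len(runs) - X.shape[1]
    residual_sd = float(np.sqrt(fit.ssr / dof)) if dof > 0 else 0.0
    return EmulatorFit(
        intercept=float(fit.params["const"]),
        coef_lnx1=float(fit.params["lnx1"]) if "lnx1" in cols else None,
        coef_lnx2=float(fit.params["lnx2"]) if "lnx2" in cols else None,
        r_squared=float(fit.rsquared),
        residual_sd=residual_sd,
    )


@dataclass(frozen=True)
class LognormalSpec:
    """Subjective effectiveness distribution: lognormal by median and spread.

    ``q975_over_median`` sets the multiplicative width: the 97.5th percentile
    is ``median * q975_over_median`` (and the 2.5th is ``median /
    q975_over_median``).  The default doubles/halves the median, mirroring
    the one-variable-at-a-time sensitivity bounds.  A point mass is
    ``q975_over_median=1``.
    """

    median: float
    q975_over_median: float = 2.0

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError("effectiveness median must be positive (log scale)")
        if self.q975_over_median < 1:
            raise ValueError("spread ratio must be >= 1")

    @property
    def sigma(self) -> float:
        return float(np.log(self.q975_over_median) / 1.959963984540054)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.median * np.exp(self.sigma * rng.standard_normal(n))


def propagate(
    fit: EmulatorFit,
    x1_distribution: LognormalSpec | None = None,
    x2_distribution: LognormalSpec | None = None,
    n_samples: int = 10_000,
    seed: int = 0,
) -> CredibilityInterval:
    """Monte-Carlo propagation of effectiveness uncertainty through the fit.

    Samples effectiveness values, evaluates the emulator, adds residual
    noise (a prediction interval for the model output), and returns the
    empirical 2.5th/97.5th percentiles truncated below at zero.
    """
    if n_samples < 1000:
        raise ValueError("n_samples must be at least 1000")
    if (fit.coef_lnx1 is not None) != (x1_distribution is not None):
        raise ValueError("x1 distribution must be given exactly when the fit uses ln(x1)")
    if (fit.coef_lnx2 is not None) != (x2_distribution is not None):
        raise ValueError("x2 distribution must be given exactly when the fit uses ln(x2)")
    rng = np.random.default_rng(seed)
    y = np.full(n_samples, fit.intercept)
    if x1_distribution is not None:
        y += fit.coef_lnx1 * np.log(x1_distribution.sample(rng, n_samples))
    if x2_distribution is not None:
        y += fit.coef_lnx2 * np.log(x2_distribution.sample(rng, n_samples))
    if fit.residual_sd > 0:
        y += fit.residual_sd * rng.standard_normal(n_samples)
    lo, hi = np.percentile(y, [2.5, 97.5])
    return CredibilityInterval(lower=max(float(lo), 0.0), upper=max(float(hi), 0.0))


def runs_to_frame(runs: Sequence[EmulatorRun]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in runs])
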