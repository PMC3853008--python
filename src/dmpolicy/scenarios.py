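"""Prevention-policy scenarios and the metrics used to compare them.

Five hypothetical national strategies are modeled:

``none``
    No prevention policy (current trends continue).
``high_risk``
    Structured lifestyle intervention for adults with both IFG and IGT;
    reduces their annual diabetes incidence by 12.5% (the product of 50%
    identified x 50% participating x 50% efficacy).
``moderate_risk``
    Lifestyle intervention for all adults with IFG (with or without IGT),
    same 12.5% net effectiveness.
``population``
    Population-wide risk-reduction policies cutting annual diabetes
    incidence by 2% in all non-diabetes states.
``combined``
    ``moderate_risk`` and ``population`` applied simultaneously; multipliers
    compose, so IFG states get (1-0.125)(1-0.02) and normal glucose (1-0.02).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import NON_DIABETES_STATES, GlucoseState

SCENARIO_NAMES = ("none", "high_risk", "moderate_risk", "population", "combined")

DEFAULT_TARGETED_EFFECTIVENESS = 0.125
DEFAULT_POPULATION_EFFECTIVENESS = 0.02


def net_effectiveness(identified: float, participates: float, efficacy: float) -> float:
    """Net incidence reduction from an identification/participation cascade.

    The "rule of halves" base case (0.5, 0.5, 0.5) yields 0.125.
    """
    for v in (identified, participates, efficacy):
        if not 0.0 <= v <= 1.0:
            raise ValueError("cascade fractions must lie in [0, 1]")
    return identified * participates * efficacy


@dataclass(frozen=True)
class InterventionScenario:
    """A policy scenario expressed as per-state incidence multipliers.

    ``targeted_effectiveness`` applies to ``target_states`` only;
    ``population_effectiveness`` applies to every non-diabetes state.  Both
    act multiplicatively on the annual diabetes incidence probabilities.
    """

    name: str
    targeted_effectiveness: float = 0.0
    population_effectiveness: float = 0.0
    target_states: tuple[GlucoseState, ...] = ()
    start_year: int | None = None

    def __post_init__(self) -> None:
        for v in (self.targeted_effectiveness, self.population_effectiveness):
            if not 0.0 <= v < 1.0:
                raise ValueError("effectiveness must lie in [0, 1)")
        for s in self.target_states:
            if s not in NON_DIABETES_STATES:
                raise ValueError(f"cannot target state {s!r}: not at risk of incident diabetes")

    def incidence_multiplier(self, state: GlucoseState) -> float:
        """Multiplier on the annual diabetes incidence out of ``state``."""
        m = 1.0 - self.population_effectiveness
        if state in self.target_states:
            m *= 1.0 - self.targeted_effectiveness
        return m

    def active_in(self, transition_start_year: int) -> bool:
        return self.start_year is None or transition_start_year >= self.start_year


def make_scenario(
    name: str,
    targeted_eff: float = DEFAULT_TARGETED_EFFECTIVENESS,
    population_eff: float = DEFAULT_POPULATION_EFFECTIVENESS,
    start_year: int | None = None,
) -> InterventionScenario:
    """Build one of the five named scenarios with given effectiveness values."""
    if name == "none":
        return InterventionScenario("none", 0.0, 0.0, (), start_year)
    if name == "high_risk":
        return InterventionScenario(
            "high_risk", targeted_eff, 0.0, (GlucoseState.IFG_IGT,), start_year
        )
    if name == "moderate_risk":
        return InterventionScenario(
            "moderate_risk",
            targeted_eff,
            0.0,
            (GlucoseState.IFG_ONLY, GlucoseState.IFG_IGT),
            start_year,
        )
    if name == "population":
        return InterventionScenario("population", 0.0, population_eff, (), start_year)
    if name == "combined":
        return InterventionScenario(
            "combined",
            targeted_eff,
            population_eff,
            (GlucoseState.IFG_ONLY, GlucoseState.IFG_IGT),
            start_year,
        )
    raise ValueError(f"unknown scenario name {name!r}; expected one of {SCENARIO_NAMES}")


def relative_attenuation(baseline, scenario, use: str = "rate") -> float:
    """Percent of the baseline 2007-to-2030 increase averted by a scenario.

    ``100 * (delta_none - delta_scenario) / delta_none`` where delta is the
    change from the first to the last projection year, computed on prevalence
    rates (``use="rate"``, the headline metric) or counts (``use="count"``).
    """
    if use == "rate":
        b = baseline.prevalence_rate
        s = scenario.prevalence_rate
    elif use == "count":
        b = baseline.diabetes_count
        s = scenario.diabetes_count
    else:
        raise ValueError("use must be 'rate' or 'count'")
    if not np.array_equal(baseline.years, scenario.years):
        raise ValueError("runs must share start year and horizon")
    d_none = b[-1] - b[0]
    d_scen = s[-1] - s[0]
    if d_none == 0:
        raise ZeroDivisionError("baseline change is zero; attenuation undefined")
    return 100.0 * (d_none - d_scen) / d_none


@dataclass
class AttenuationSummary:
    """Per-scenario comparison metrics against the no-intervention run."""

    scenario: str
    prevented_cumulative_cases: float
    prevented_prevalent_cases_2030: float
    rate_2030: float
    change_2007_2030_pp: float
    relative_attenuation_rate: float
    relative_attenuation_count: float


def compare_scenarios(results: dict) -> pd.DataFrame:
    """Build the scenario-comparison table from named projection results.

    ``results`` maps scenario name to :class:`~dmpolicy.states.ProjectionResult`
    and must contain the ``"none"`` run all others are compared against.
    """
    if "none" not in results:
        raise KeyError("comparison requires the 'none' scenario run")
    base = results["none"]
    rows = []
    for name, res in results.items():
        att_rate = att_count = 0.0
        if name != "none":
            att_rate = relative_attenuation(base, res, use="rate")
            att_count = relative_attenuation(base, res, use="count")
        rows.append(
            AttenuationSummary(
                scenario=name,
                prevented_cumulative_cases=base.cumulative_incidence[-1]
                - res.cumulative_incidence[-1],
                prevented_prevalent_cases_2030=base.diabetes_count[-1]
                - res.diabetes_count[-1],
                rate_2030=res.prevalence_rate[-1],
                change_2007_2030_pp=100.0
                * (res.prevalence_rate[-1] - res.prevalence_rate[0]),
                relative_attenuation_rate=att_rate,
                relative_attenuation_count=att_count,
            ).__dict__
        )
    return pd.DataFrame(rows)
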