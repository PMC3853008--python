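"""Discrete-time five-state projection engine.

The population evolves by the annual difference equation

    N(t) = N(t-1) P(t) + B(t) + M(t)

where ``N`` is the row vector of state counts, ``P(t)`` the 5x5 transition
matrix, and ``B``/``M`` entrant vectors (aging-in "births" and net
migration).  Rows of ``P`` sum to one minus the state's death probability;
death probabilities are the base rate times the mortality relative risks
(1, 1, 1, 1.77, 2.11).  Transitions out of diabetes are structurally zero.

Flows out of each non-diabetes state ``i``:

* diabetes incidence ``inc_i = lambda_i * scale * growth^(t - t0) * m_i``,
  where ``m_i`` is the scenario's incidence multiplier for state ``i``;
  split between undiagnosed and diagnosed destinations by the
  diagnosed-at-onset fraction;
* stage progression NORMAL -> IFG_ONLY and IFG_ONLY -> IFG_IGT;
* undiagnosed diabetes is detected (moves to diagnosed) at a constant rate.

Probability mass freed by an intervention's incidence reduction stays on the
diagonal (people remain in their current state).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .demography import DemographySchedule
from .parameters import EpidemiologicParameters
from .scenarios import InterventionScenario, make_scenario
from .states import (
    DIABETES_STATES,
    N_STATES,
    NON_DIABETES_STATES,
    GlucoseState,
    ProjectionResult,
    StateVector,
    TransitionMatrix,
)

_NON_DM = [int(s) for s in NON_DIABETES_STATES]
_DM = [int(s) for s in DIABETES_STATES]

_NO_INTERVENTION = make_scenario("none")


def mortality_rates(params: EpidemiologicParameters, base_death_rate: float) -> np.ndarray:
    """Per-state annual death probabilities: base rate times relative risks."""
    rr = np.array([1.0, 1.0, 1.0, params.rr_undiag, params.rr_diag])
    return base_death_rate * rr


def build_transition_matrix(
    params: EpidemiologicParameters,
    base_death_rate: float,
    scenario: InterventionScenario | None = None,
    year: int = 0,
    growth_reference_year: int | None = None,
) -> TransitionMatrix:
    """Assemble the one-year transition matrix for the transition into ``year``.

    ``growth_reference_year`` anchors the incidence trend: the exponent on
    ``incidence_growth`` is the number of years from that anchor to the start
    of the transition (``year - 1``).  With the default anchor the exponent
    is zero, i.e. untrended rates.
    """
    if scenario is None:
        scenario = _NO_INTERVENTION
    if not 0.0 <= base_death_rate <= 1.0:
        raise ValueError("base death rate must lie in [0, 1]")
    d = mortality_rates(params, base_death_rate)
    if np.any(d > 1.0):
        raise ValueError("relative risk drives a death probability above 1")

    transition_start = year - 1
    exponent = 0 if growth_reference_year is None else transition_start - growth_reference_year
    growth = params.incidence_growth ** max(exponent, 0)
    active = scenario.active_in(transition_start)

    f = params.diagnosed_at_onset_fraction
    p = np.zeros((N_STATES, N_STATES))
    p[GlucoseState.NORMAL, GlucoseState.IFG_ONLY] = params.prog_normal_to_ifg
    p[GlucoseState.IFG_ONLY, GlucoseState.IFG_IGT] = params.prog_ifg_to_ifgigt
    for state, lam in zip(NON_DIABETES_STATES, params.stratum_incidence):
        mult = scenario.incidence_multiplier(state) if active else 1.0
        inc = lam * params.incidence_scale * growth * mult
        p[state, GlucoseState.UNDIAG_DM] = inc * (1.0 - f)
        p[state, GlucoseState.DIAG_DM] = inc * f
    p[GlucoseState.UNDIAG_DM, GlucoseState.DIAG_DM] = params.detection_rate

    for i in range(N_STATES):
        diag = 1.0 - d[i] - p[i].sum()
        if diag < 0:
            raise ValueError(
                f"outflow from {GlucoseState(i).name} exceeds survival "
                f"probability (diagonal would be {diag:.4f})"
            )
        p[i, i] = diag

    m = TransitionMatrix(year=year, p=p, death_rates=d)
    m.validate()
    return m


def step(
    state: StateVector,
    matrix: TransitionMatrix,
    births: np.ndarray | None = None,
    migration: np.ndarray | None = None,
) -> StateVector:
    """Advance the state vector one year: ``N(t) = N(t-1) P(t) + B + M``."""
    if matrix.year != state.year + 1:
        raise ValueError(
            f"matrix is for the transition into {matrix.year}, state is at {state.year}"
        )
    b = np.zeros(N_STATES) if births is None else np.asarray(births, dtype=float)
    m = np.zeros(N_STATES) if migration is None else np.asarray(migration, dtype=float)
    new = state.counts @ matrix.p + b + m
    if np.any(new < 0):
        raise ValueError(
            "negative population count after step: demography inconsistent "
            f"with transition flows at {matrix.year}"
        )
    return StateVector(year=state.year + 1, counts=new)


def _entrants(
    post_transition: np.ndarray,
    target_total: float,
    migration_fraction: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the entrant flow required to hit the population target.

    Births enter NORMAL; migration is allocated proportionally to the current
    (post-transition) state mix.
    """
    entrant_total = target_total - post_transition.sum()
    if entrant_total < 0:
        raise ValueError("population target below survivor count; demography inconsistent")
    births = np.zeros(N_STATES)
    births[GlucoseState.NORMAL] = (1.0 - migration_fraction) * entrant_total
    migration = post_transition / post_transition.sum() * migration_fraction * entrant_total
    return births, migration


def project(
    initial: StateVector,
    params: EpidemiologicParameters,
    demography: DemographySchedule,
    scenario: InterventionScenario | None = None,
    end_year: int | None = None,
) -> ProjectionResult:
    """Run the projection from ``initial.year`` through ``end_year``.

    Cumulative incidence accumulates every transition from a non-diabetes
    state into either diabetes state.  Deaths and entrants are recorded per
    year; when the schedule carries a ``migration_fraction`` the entrants are
    re-derived each year against the schedule's population targets (the
    Census-consistency constraint), otherwise its stored vectors are used.
    """
    if scenario is None:
        scenario = _NO_INTERVENTION
    end_year = demography.end_year if end_year is None else int(end_year)
    if end_year <= initial.year:
        raise ValueError("end_year must be after the initial year")
    if not demography.covers(initial.year, end_year):
        raise ValueError(
            f"demography schedule {demography.start_year}-{demography.end_year} "
            f"does not cover {initial.year}-{end_year}"
        )

    states = [initial]
    n_years = end_year - initial.year + 1
    cum = np.zeros(n_years)
    deaths = np.zeros((n_years, N_STATES))
    entrants = np.zeros((n_years, N_STATES))

    current = initial
    for year in range(initial.year + 1, end_year + 1):
        k = demography.transition_index(year)
        matrix = build_transition_matrix(
            params,
            base_death_rate=float(demography.base_death_rate[k]),
            scenario=scenario,
            year=year,
            growth_reference_year=initial.year,
        )
        post = current.counts @ matrix.p
        if demography.migration_fraction is not None:
            births, migration = _entrants(
                post, demography.total_at(year), demography.migration_fraction
            )
        else:
            births, migration = demography.births[k], demography.migration[k]
        i = year - initial.year
        deaths[i] = current.counts * matrix.death_rates
        entrants[i] = births + migration
        inflow = float(
            current.counts[_NON_DM] @ (matrix.p[_NON_DM][:, _DM]).sum(axis=1)
        )
        cum[i] = cum[i - 1] + inflow
        current = step(current, matrix, births, migration)
        states.append(current)

    return ProjectionResult(
        states=states,
        cumulative_incidence=cum,
        deaths=deaths,
        scenario_name=scenario.name,
        entrants=entrants,
    )


def cumulative_incidence_series(result: ProjectionResult) -> pd.Series:
    """Per-year running total of new diabetes cases (millions)."""
    if len(result.states) < 2:
        raise ValueError("result must span at least one transition")
    return pd.Series(
        result.cumulative_incidence, index=result.years, name="cumulative_incidence_millions"
    )
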