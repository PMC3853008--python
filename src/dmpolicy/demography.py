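"""Demographic schedule driving the projection: totals, entrants, mortality.

The projection is constrained to externally given total-population targets
(back-derived from published count/rate pairs, emulating Census projections).
A schedule stores, per one-year transition, the base (non-diabetes) death
probability and the entrant vectors — "births" (adults aging into the 20+
population, assumed normoglycemic) and net migration.

When ``migration_fraction`` is set, a projection run re-derives the entrant
vectors each year so its total matches ``total_population`` exactly: the
entrant total is whatever the target requires after survival, split into
births (into NORMAL) and migration (allocated proportionally to the current
state mix).  Population totals are exogenous to diabetes policy, so the same
targets constrain every scenario run.  With ``migration_fraction=None`` the
stored ``births``/``migration`` rows are used verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .states import N_STATES


@dataclass
class DemographySchedule:
    years: np.ndarray
    total_population: np.ndarray
    births: np.ndarray
    migration: np.ndarray
    base_death_rate: np.ndarray
    migration_fraction: float | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.total_population = np.asarray(self.total_population, dtype=float)
        n = len(self.years)
        if self.total_population.shape != (n,):
            raise ValueError("one total per year required")
        if np.any(self.total_population <= 0):
            raise ValueError("population totals must be strictly positive")
        self.births = np.asarray(self.births, dtype=float).reshape(n - 1, N_STATES)
        self.migration = np.asarray(self.migration, dtype=float).reshape(n - 1, N_STATES)
        self.base_death_rate = np.asarray(self.base_death_rate, dtype=float)
        if self.base_death_rate.shape != (n - 1,):
            raise ValueError("one base death rate per transition required")

    @property
    def start_year(self) -> int:
        return int(self.years[0])

    @property
    def end_year(self) -> int:
        return int(self.years[-1])

    def covers(self, start: int, end: int) -> bool:
        return self.start_year <= start and end <= self.end_year

    def transition_index(self, into_year: int) -> int:
        """Index of the transition ending at ``into_year``."""
        k = int(into_year - self.start_year) - 1
        if not 0 <= k < len(self.base_death_rate):
            raise KeyError(f"schedule does not cover the transition into {into_year}")
        return k

    def total_at(self, year: int) -> float:
        idx = int(year - self.start_year)
        if not 0 <= idx < len(self.years):
            raise KeyError(f"schedule does not cover {year}")
        return float(self.total_population[idx])
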