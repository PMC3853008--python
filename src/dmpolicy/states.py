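"""Glucose-state space and the containers the projection engine operates on.

The model partitions the US adult (20+) population into five mutually
exclusive glycemic states.  ``IFG_ONLY`` and ``IFG_IGT`` together make up
"IFG regardless of IGT status": an adult with impaired fasting glucose is in
``IFG_IGT`` when they additionally have impaired glucose tolerance, and in
``IFG_ONLY`` otherwise.  The two diabetes states are absorbing with respect
to glycemia (no remission), except for death.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd


class GlucoseState(IntEnum):
    """The five glycemic states, in transition-matrix row/column order."""

    NORMAL = 0
    IFG_ONLY = 1
    IFG_IGT = 2
    UNDIAG_DM = 3
    DIAG_DM = 4


N_STATES = len(GlucoseState)

#: States without diabetes, i.e. the pool at risk of incident diabetes.
NON_DIABETES_STATES = (
    GlucoseState.NORMAL,
    GlucoseState.IFG_ONLY,
    GlucoseState.IFG_IGT,
)

#: The two diabetes states (prevalent diabetes = their sum).
DIABETES_STATES = (GlucoseState.UNDIAG_DM, GlucoseState.DIAG_DM)

_NON_DM = [int(s) for s in NON_DIABETES_STATES]
_DM = [int(s) for s in DIABETES_STATES]


@dataclass
class StateVector:
    """Population counts (millions of adults) per glucose state at one year."""

    year: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_STATES,):
            raise ValueError(f"counts must have shape ({N_STATES},)")
        if np.any(self.counts < 0):
            raise ValueError("state counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def diabetes_count(self) -> float:
        """Prevalent diabetes, diagnosed plus undiagnosed (millions)."""
        return float(self.counts[_DM].sum())

    @property
    def non_diabetes_count(self) -> float:
        return float(self.counts[_NON_DM].sum())

    @property
    def prevalence_rate(self) -> float:
        return self.diabetes_count / self.total

    @property
    def diagnosed_share_of_dm(self) -> float:
        return float(self.counts[GlucoseState.DIAG_DM]) / self.diabetes_count


@dataclass
class TransitionMatrix:
    """One-year transition probabilities between glucose states.

    ``p[i, j]`` is the probability of being in state ``j`` at ``year`` given
    state ``i`` the year before.  Rows sum to ``1 - death_rates[i]``; entries
    that are impossible (remission, leaving diagnosed diabetes) are
    structural zeros.
    """

    year: int
    p: np.ndarray
    death_rates: np.ndarray

    #: (row, col) pairs fixed to zero by the model's no-remission assumptions.
    STRUCTURAL_ZEROS = tuple(
        (i, j)
        for i in _DM
        for j in _NON_DM
    ) + ((4, 3),)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.death_rates = np.asarray(self.death_rates, dtype=float)

    def validate(self, atol: float = 1e-12) -> None:
        if self.p.shape != (N_STATES, N_STATES):
            raise ValueError("p must be 5x5")
        if np.any(self.p < -atol) or np.any(self.p > 1 + atol):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if np.any(self.death_rates < -atol) or np.any(self.death_rates > 1 + atol):
            raise ValueError("death rates must lie in [0, 1]")
        rowsum = self.p.sum(axis=1)
        if not np.allclose(rowsum, 1.0 - self.death_rates, atol=1e-9):
            raise ValueError("rows must sum to one minus the state death rate")
        for i, j in self.STRUCTURAL_ZEROS:
            if self.p[i, j] != 0.0:
                raise ValueError(f"structural zero violated at ({i}, {j})")


@dataclass
class ProjectionResult:
    """Yearly output of a projection run.

    Attributes
    ----------
    states
        One ``StateVector`` per calendar year, start year included.
    cumulative_incidence
        Running total (millions) of transitions from non-diabetes into either
        diabetes state, counted from the start year (0 at the start year).
    deaths
        Per-state deaths (millions) occurring during the transition into each
        year; zeros for the start year.
    """

    states: list[StateVector]
    cumulative_incidence: np.ndarray
    deaths: np.ndarray
    scenario_name: str = "none"
    entrants: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def years(self) -> np.ndarray:
        return np.array([s.year for s in self.states])

    @property
    def counts(self) -> np.ndarray:
        """(n_years, 5) array of state counts in millions."""
        return np.vstack([s.counts for s in self.states])

    @property
    def total_population(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def diabetes_count(self) -> np.ndarray:
        return self.counts[:, _DM].sum(axis=1)

    @property
    def prevalence_rate(self) -> np.ndarray:
        return self.diabetes_count / self.total_population

    def at(self, year: int) -> StateVector:
        idx = int(year - self.states[0].year)
        if not 0 <= idx < len(self.states):
            raise KeyError(f"year {year} outside projection horizon")
        return self.states[idx]

    def cumulative_incidence_at(self, year: int) -> float:
        return float(self.cumulative_incidence[int(year - self.states[0].year)])

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-year, per-state table of the run."""
        rows = []
        for k, sv in enumerate(self.states):
            for s in GlucoseState:
                rows.append(
                    {
                        "year": sv.year,
                        "state": s.name,
                        "count_millions": sv.counts[int(s)],
                        "prevalence_rate": sv.prevalence_rate,
                        "cumulative_incidence_millions": self.cumulative_incidence[k],
                        "scenario": self.scenario_name,
                    }
                )
        return pd.DataFrame(rows)
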