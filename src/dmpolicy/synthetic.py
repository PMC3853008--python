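"""Synthetic demography and parameter sets for testing the pipeline.

Stands in for the census/survey inputs: geometric population growth with
multiplicative lognormal noise, entrants derived to be consistent with the
totals under a nominal death rate, and multiplicatively jittered
epidemiologic parameters.  Every generator is a pure function of its spec
(including the seed).  The defaults emulate the US adult population over the
2007-2030 horizon: 215.5 million adults growing ~0.94%/yr to 267.4 million.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import DemographySchedule
from .parameters import EpidemiologicParameters, PrevalenceInputs
from .states import N_STATES, GlucoseState, StateVector, TransitionMatrix

US_GROWTH_2007_2030 = (267.4 / 215.5) ** (1.0 / 23.0) - 1.0


@dataclass(frozen=True)
class SyntheticSpec:
    start_year: int = 2007
    end_year: int = 2030
    start_population: float = 215.5
    annual_growth: float = US_GROWTH_2007_2030
    growth_noise_sd: float = 0.0
    prevalence_perturbation: float = 0.0
    nominal_death_rate: float = 0.01
    migration_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise ValueError("end_year must exceed start_year")
        if self.start_population <= 0:
            raise ValueError("start_population must be positive")
        if self.growth_noise_sd < 0 or self.prevalence_perturbation < 0:
            raise ValueError("noise standard deviations must be >= 0")


def generate_demography(spec: SyntheticSpec) -> DemographySchedule:
    """Geometric totals with lognormal noise and target-consistent entrants.

    Entrant totals are set so that, at the nominal death rate, the
    year-over-year change in totals is honored exactly; the schedule carries
    ``migration_fraction`` so projections re-derive entrants against the
    totals (the same constraint used by the calibrated schedule).
    """
    rng = np.random.default_rng(spec.seed)
    years = np.arange(spec.start_year, spec.end_year + 1)
    n = len(years)
    growth = (1.0 + spec.annual_growth) ** np.arange(n)
    noise = np.exp(
        spec.growth_noise_sd * rng.standard_normal(n) - 0.5 * spec.growth_noise_sd**2
    ) if spec.growth_noise_sd > 0 else np.ones(n)
    noise[0] = 1.0
    totals = spec.start_population * growth * noise

    births = np.zeros((n - 1, N_STATES))
    migration = np.zeros((n - 1, N_STATES))
    for k in range(n - 1):
        entrant_total = totals[k + 1] - totals[k] * (1.0 - spec.nominal_death_rate)
        entrant_total = max(entrant_total, 0.0)
        births[k, GlucoseState.NORMAL] = (1.0 - spec.migration_fraction) * entrant_total
        migration[k, GlucoseState.NORMAL] = spec.migration_fraction * entrant_total
    return DemographySchedule(
        years=years,
        total_population=totals,
        births=births,
        migration=migration,
        base_death_rate=np.full(n - 1, spec.nominal_death_rate),
        migration_fraction=spec.migration_fraction,
    )


def generate_parameter_set(spec: SyntheticSpec) -> EpidemiologicParameters:
    """Base-case parameters, multiplicatively jittered.

    With zero perturbation this returns exactly the printed base case.  The
    stratum-incidence ordering (normal < IFG < IFG+IGT) is enforced by
    rejection sampling.
    """
    base = EpidemiologicParameters()
    if spec.prevalence_perturbation == 0:
        return base
    rng = np.random.default_rng(spec.seed)
    sd = spec.prevalence_perturbation
    for _ in range(1000):
        jitter = np.exp(sd * rng.standard_normal(5))
        lam = np.array(base.stratum_incidence) * jitter[:3]
        if not (lam[0] < lam[1] < lam[2] and np.all(lam < 1)):
            continue
        return base.with_(
            lambda_normal=float(lam[0]),
            lambda_ifg=float(lam[1]),
            lambda_ifgigt=float(lam[2]),
            rr_undiag=float(base.rr_undiag * jitter[3]),
            rr_diag=float(base.rr_diag * jitter[4]),
        )
    raise RuntimeError("rejection sampling failed to order stratum incidences")


def generate_initial_state(spec: SyntheticSpec) -> StateVector:
    """2007-like initial state, optionally with perturbed shares."""
    inputs = PrevalenceInputs()
    shares = np.array(
        [
            1.0 - inputs.total_dm_rate - inputs.ifg_rate_any,
            inputs.ifg_rate_any - inputs.ifg_igt_rate,
            inputs.ifg_igt_rate,
            inputs.total_dm_rate * (1.0 - inputs.diagnosed_share_of_dm),
            inputs.total_dm_rate * inputs.diagnosed_share_of_dm,
        ]
    )
    if spec.prevalence_perturbation > 0:
        rng = np.random.default_rng(spec.seed + 1)
        shares = shares * np.exp(spec.prevalence_perturbation * rng.standard_normal(5))
        shares /= shares.sum()
    return StateVector(year=spec.start_year, counts=shares * spec.start_population)


def generate_toy_fixture() -> tuple[StateVector, TransitionMatrix, DemographySchedule]:
    """Tiny hand-checkable instance: round numbers, 3-year horizon.

    100 people in NORMAL; each year 10% progress to IFG_ONLY, 5% of IFG_ONLY
    develop (undiagnosed) diabetes, nobody dies; totals grow by exactly the
    entrant inflow of 2 into NORMAL per year.
    """
    initial = StateVector(year=2000, counts=np.array([100.0, 0.0, 0.0, 0.0, 0.0]))
    p = np.eye(N_STATES)
    p[GlucoseState.NORMAL, GlucoseState.NORMAL] = 0.9
    p[GlucoseState.NORMAL, GlucoseState.IFG_ONLY] = 0.1
    p[GlucoseState.IFG_ONLY, GlucoseState.IFG_ONLY] = 0.95
    p[GlucoseState.IFG_ONLY, GlucoseState.UNDIAG_DM] = 0.05
    matrix = TransitionMatrix(year=2001, p=p, death_rates=np.zeros(N_STATES))
    matrix.validate()
    years = np.arange(2000, 2004)
    births = np.zeros((3, N_STATES))
    births[:, GlucoseState.NORMAL] = 2.0
    schedule = DemographySchedule(
        years=years,
        total_population=100.0 + 2.0 * np.arange(4),
        births=births,
        migration=np.zeros((3, N_STATES)),
        base_death_rate=np.zeros(3),
        migration_fraction=None,
    )
    return initial, matrix, schedule
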