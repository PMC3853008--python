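"""Calibration of everything the published inputs leave implicit.

The printed inputs pin the 2007 state mix, the stratum incidence rates, and
the mortality relative risks.  Everything else the dynamics need is solved
here so that the no-intervention run satisfies the published constraints:

* **Population targets.**  Total adult population per year is back-derived
  from published count/rate pairs (count / rate) at six anchor years and
  geometrically interpolated — the Census-consistency constraint expressed
  through published outputs.
* **Base mortality.**  One base (non-diabetes) death probability per year,
  derived by inverting an effective crude death rate through the current
  state mix and the fixed relative risks.  The crude level itself is a
  fitted scalar: in a homogeneous (non age-structured) model it is an
  effective parameter, not the demographic crude rate.
* **Entrants.**  The entrant flow each year is whatever the population
  target requires after survival; a fitted ``migration_fraction`` splits it
  into aging-in births (into NORMAL) and net migration (allocated
  proportionally to the current mix).
* **Detection and diagnosed-at-onset.**  Solved so the diagnosed share of
  total diabetes stays at its target (default 16.3/22.7 = 0.718, the only
  year the split is printed) across the horizon.
* **Progression rates.**  NORMAL->IFG and IFG->IFG+IGT probabilities solved
  so the prediabetes strata keep their initial shares of the non-diabetic
  population (quasi-stationarity).
* **Incidence scale.**  A common multiplier on the three stratum incidences,
  fitted to the published cumulative-incidence trajectory; it absorbs the
  stated gap between the stratum rates (~1.09%/yr overall) and the overall
  1.22%/yr starting incidence.

All unknowns are solved jointly by deterministic nonlinear least squares on
the no-intervention run only; scenario outputs are never fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .demography import DemographySchedule
from .model import build_transition_matrix, mortality_rates, project
from .parameters import EpidemiologicParameters, PrevalenceInputs
from .states import (
    DIABETES_STATES,
    N_STATES,
    NON_DIABETES_STATES,
    GlucoseState,
    StateVector,
)

_NON_DM = [int(s) for s in NON_DIABETES_STATES]
_DM = [int(s) for s in DIABETES_STATES]

# Published no-intervention projection anchors (counts in millions, rates as
# fractions, cumulative incident cases in millions).  The start-year
# cumulative entry is excluded from fitting: its printed value is offset by
# one transition relative to the later columns.
ANCHOR_YEARS = np.array([2007, 2010, 2015, 2020, 2025, 2030])
ANCHOR_COUNTS = np.array([27.8, 33.1, 41.2, 48.7, 55.3, 60.7])
ANCHOR_RATES = np.array([0.129, 0.148, 0.175, 0.197, 0.215, 0.227])
ANCHOR_CUMULATIVE = np.array([2.3, 6.8, 17.9, 29.1, 40.3, 51.7])

START_YEAR = 2007
END_YEAR = 2030


def derive_population_targets(
    prevalence_counts: np.ndarray,
    prevalence_rates: np.ndarray,
    anchor_years: np.ndarray = ANCHOR_YEARS,
) -> pd.Series:
    """Back-derive total population per year from count/rate anchor pairs.

    Anchor-year totals are ``count / rate``; intermediate years are filled by
    geometric interpolation (population growth is multiplicative).
    """
    counts = np.asarray(prevalence_counts, dtype=float)
    rates = np.asarray(prevalence_rates, dtype=float)
    years = np.asarray(anchor_years, dtype=int)
    if len(counts) < 2 or len(counts) != len(rates) or len(counts) != len(years):
        raise ValueError("need matching counts and rates for at least two anchor years")
    if np.any(rates <= 0) or np.any(rates >= 1):
        raise ValueError("prevalence rates must lie in (0, 1)")
    totals = counts / rates
    grid = np.arange(years[0], years[-1] + 1)
    interp = np.exp(np.interp(grid, years, np.log(totals)))
    return pd.Series(interp, index=grid, name="total_population_millions")


def build_initial_state(inputs: PrevalenceInputs, total_population: float) -> StateVector:
    """Initial state vector from printed prevalence fractions."""
    ifg_only = inputs.ifg_rate_any - inputs.ifg_igt_rate
    normal = 1.0 - inputs.total_dm_rate - inputs.ifg_rate_any
    shares = np.array(
        [
            normal,
            ifg_only,
            inputs.ifg_igt_rate,
            inputs.total_dm_rate * (1.0 - inputs.diagnosed_share_of_dm),
            inputs.total_dm_rate * inputs.diagnosed_share_of_dm,
        ]
    )
    if np.any(shares < 0):
        raise ValueError("printed prevalences imply a negative state share")
    return StateVector(year=inputs.year, counts=shares * total_population)


def crude_to_base_rate(
    crude_rate: float, state_shares: np.ndarray, params: EpidemiologicParameters
) -> float:
    """Invert a population crude death rate through the state mix.

    With relative risks ``rr_i`` and state shares ``w_i``, the base rate that
    yields the crude rate is ``crude / sum(w_i rr_i)``.
    """
    rr = np.array([1.0, 1.0, 1.0, params.rr_undiag, params.rr_diag])
    return float(crude_rate / (np.asarray(state_shares) @ rr))


def solve_base_mortality(
    demography: DemographySchedule,
    params: EpidemiologicParameters,
    states: list[StateVector],
) -> np.ndarray:
    """Per-year base death rates implied by population targets and entrants.

    For each transition, total deaths must equal ``total(N(t-1)) + B + M -
    target(t)``; with per-state deaths ``N_i * base * rr_i`` the base rate is
    that requirement divided by ``sum(N_i rr_i)``.
    """
    rr = np.array([1.0, 1.0, 1.0, params.rr_undiag, params.rr_diag])
    rates = np.zeros(len(states) - 1)
    for k, sv in enumerate(states[:-1]):
        year = sv.year + 1
        required = (
            sv.total
            + demography.births[k].sum()
            + demography.migration[k].sum()
            - demography.total_at(year)
        )
        base = required / float(sv.counts @ rr)
        if not 0.0 <= base <= 0.1:
            raise ValueError(
                f"implied base death rate {base:.4f} for {year} outside [0, 0.1]"
            )
        rates[k] = base
    return rates


def _baseline_run(
    initial: StateVector,
    params: EpidemiologicParameters,
    totals: pd.Series,
    crude_rate: float,
    migration_fraction: float,
):
    """No-intervention run deriving demography on the fly.

    Returns state counts (n_years x 5), cumulative incidence, and the
    per-transition base death rates / births / migration it implies.
    """
    years = totals.index.to_numpy()
    n = len(years)
    counts = np.zeros((n, N_STATES))
    counts[0] = initial.counts
    cum = np.zeros(n)
    base_rates = np.zeros(n - 1)
    births = np.zeros((n - 1, N_STATES))
    migration = np.zeros((n - 1, N_STATES))
    for k in range(n - 1):
        cur = counts[k]
        base = crude_to_base_rate(crude_rate, cur / cur.sum(), params)
        matrix = build_transition_matrix(
            params,
            base_death_rate=base,
            year=int(years[k + 1]),
            growth_reference_year=int(years[0]),
        )
        post = cur @ matrix.p
        entrant_total = totals.iloc[k + 1] - post.sum()
        b = np.zeros(N_STATES)
        b[GlucoseState.NORMAL] = (1.0 - migration_fraction) * entrant_total
        m = post / post.sum() * migration_fraction * entrant_total
        counts[k + 1] = post + b + m
        cum[k + 1] = cum[k] + float(cur[_NON_DM] @ matrix.p[_NON_DM][:, _DM].sum(axis=1))
        base_rates[k] = base
        births[k] = b
        migration[k] = m
    return counts, cum, base_rates, births, migration


def solve_detection_and_onset(
    params: EpidemiologicParameters,
    diagnosed_share_target: float,
    demography: DemographySchedule,
    initial: StateVector,
    check_years: tuple[int, int] | None = None,
    targets: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Solve detection rate and diagnosed-at-onset fraction.

    The pair is chosen so the diagnosed share of total diabetes equals its
    target at two checkpoint years (mid-horizon and end by default) under
    no-intervention dynamics, which holds the share stable across the
    horizon.  For recovery from an observed run, per-checkpoint ``targets``
    may be supplied instead of a single stable share.
    """
    if not 0.0 < diagnosed_share_target < 1.0:
        raise ValueError("diagnosed share target must lie in (0, 1)")
    start, end = initial.year, demography.end_year
    if check_years is None:
        check_years = ((start + end) // 2, end)
    if targets is None:
        targets = (diagnosed_share_target, diagnosed_share_target)

    def residual(x):
        q, f = x
        trial = params.with_(detection_rate=float(q), diagnosed_at_onset_fraction=float(f))
        res = project(initial, trial, demography)
        out = []
        for year, tgt in zip(check_years, targets):
            sv = res.at(year)
            out.append(sv.diagnosed_share_of_dm - tgt)
        return out

    sol = optimize.least_squares(
        residual,
        [0.02, 0.5],
        bounds=([0.0, 0.0], [1.0, 1.0]),
        xtol=1e-12,
        ftol=1e-12,
    )
    resid = np.asarray(residual(sol.x))
    if np.any(np.abs(resid) > 0.02):
        raise ValueError(
            "no (detection, onset) pair in [0,1]^2 holds the diagnosed share "
            f"within +/-0.02 of target (best residuals {resid})"
        )
    return float(sol.x[0]), float(sol.x[1])


def solve_progression_rates(
    params: EpidemiologicParameters,
    demography: DemographySchedule,
    initial: StateVector,
    target_shares: tuple[float, float] | None = None,
    check_year: int | None = None,
) -> tuple[float, float]:
    """Solve NORMAL->IFG and IFG->IFG+IGT progression probabilities.

    Defaults enforce quasi-stationarity: at the check year (end of horizon)
    the IFG_ONLY and IFG_IGT shares of the non-diabetic population equal
    their initial values.  Observed shares may be supplied for recovery.
    """
    check_year = demography.end_year if check_year is None else check_year
    init_non_dm = initial.counts[_NON_DM].sum()
    if target_shares is None:
        target_shares = (
            initial.counts[GlucoseState.IFG_ONLY] / init_non_dm,
            initial.counts[GlucoseState.IFG_IGT] / init_non_dm,
        )

    def residual(x):
        p01, p12 = x
        trial = params.with_(
            prog_normal_to_ifg=float(p01), prog_ifg_to_ifgigt=float(p12)
        )
        res = project(initial, trial, demography)
        sv = res.at(check_year)
        non_dm = sv.counts[_NON_DM].sum()
        return [
            sv.counts[GlucoseState.IFG_ONLY] / non_dm - target_shares[0],
            sv.counts[GlucoseState.IFG_IGT] / non_dm - target_shares[1],
        ]

    sol = optimize.least_squares(
        residual, [0.02, 0.01], bounds=([0.0, 0.0], [1.0, 1.0]), xtol=1e-12, ftol=1e-12
    )
    resid = np.asarray(residual(sol.x))
    if np.any(np.abs(resid) > 0.1 * np.asarray(target_shares)):
        raise ValueError(
            "quasi-stationarity system infeasible in [0,1]^2 "
            f"(best residuals {resid})"
        )
    return float(sol.x[0]), float(sol.x[1])


@dataclass
class CalibrationResult:
    """Solved parameters plus the frozen demographic schedule."""

    params: EpidemiologicParameters
    demography: DemographySchedule
    initial: StateVector
    crude_death_rate: float
    migration_fraction: float
    diagnosed_share_target: float
    residuals: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def report(self) -> dict:
        return {
            "solved": {
                "detection_rate": self.params.detection_rate,
                "diagnosed_at_onset_fraction": self.params.diagnosed_at_onset_fraction,
                "prog_normal_to_ifg": self.params.prog_normal_to_ifg,
                "prog_ifg_to_ifgigt": self.params.prog_ifg_to_ifgigt,
                "crude_death_rate": self.crude_death_rate,
                "migration_fraction": self.migration_fraction,
                "incidence_scale": self.params.incidence_scale,
            },
            "targets": {"diagnosed_share": self.diagnosed_share_target},
            "residuals": self.residuals,
            "diagnostics": self.diagnostics,
        }


def calibrate(
    inputs: PrevalenceInputs | None = None,
    params: EpidemiologicParameters | None = None,
    anchor_years: np.ndarray = ANCHOR_YEARS,
    anchor_counts: np.ndarray = ANCHOR_COUNTS,
    anchor_rates: np.ndarray = ANCHOR_RATES,
    anchor_cumulative: np.ndarray = ANCHOR_CUMULATIVE,
) -> CalibrationResult:
    """Jointly solve all implicit parameters against the published anchors.

    Seven unknowns (detection, diagnosed-at-onset, two progressions,
    effective crude death rate, migration fraction, incidence scale) are fit
    by deterministic least squares to: prevalence counts and cumulative
    incidence at the 2010-2030 anchors, diagnosed share at mid-horizon and
    end, and prediabetes stratum-share stationarity at mid-horizon and end,
    each residual scaled by its stated tolerance.
    """
    inputs = inputs or PrevalenceInputs()
    params = params or EpidemiologicParameters()
    totals = derive_population_targets(anchor_counts, anchor_rates, anchor_years)
    initial = build_initial_state(inputs, totals.iloc[0])
    years = totals.index.to_numpy()
    anchor_idx = [int(y - years[0]) for y in anchor_years]
    init_non_dm_shares = (
        initial.counts[GlucoseState.IFG_ONLY] / initial.counts[_NON_DM].sum(),
        initial.counts[GlucoseState.IFG_IGT] / initial.counts[_NON_DM].sum(),
    )
    mid_idx = (len(years) - 1) // 2
    dtarget = inputs.diagnosed_share_of_dm

    def unpack(x):
        q, f, p01, p12, crude, migfrac, scale = x
        return (
            params.with_(
                detection_rate=float(q),
                diagnosed_at_onset_fraction=float(f),
                prog_normal_to_ifg=float(p01),
                prog_ifg_to_ifgigt=float(p12),
                incidence_scale=float(scale),
            ),
            float(crude),
            float(migfrac),
        )

    def residual(x):
        trial, crude, migfrac = unpack(x)
        counts, cum, *_ = _baseline_run(initial, trial, totals, crude, migfrac)
        dm = counts[:, _DM].sum(axis=1)
        diag_share = counts[:, GlucoseState.DIAG_DM] / dm
        non_dm = counts[:, _NON_DM].sum(axis=1)
        # Heterogeneous targets are weighted by their stated tolerances so a
        # unit residual means "at tolerance": diagnosed share +/-0.02,
        # stratum-share drift +/-10% relative, anchors +/-5% relative.
        r = [
            (diag_share[mid_idx] - dtarget) / 0.02,
            (diag_share[-1] - dtarget) / 0.02,
        ]
        for idx in (mid_idx, len(counts) - 1):
            r.append(
                (counts[idx, GlucoseState.IFG_ONLY] / non_dm[idx] / init_non_dm_shares[0] - 1.0)
                / 0.10
            )
            r.append(
                (counts[idx, GlucoseState.IFG_IGT] / non_dm[idx] / init_non_dm_shares[1] - 1.0)
                / 0.10
            )
        for j, idx in enumerate(anchor_idx):
            if idx == 0:
                continue
            r.append((dm[idx] - anchor_counts[j]) / anchor_counts[j] / 0.05)
            r.append((cum[idx] - anchor_cumulative[j]) / anchor_cumulative[j] / 0.05)
        return r

    sol = optimize.least_squares(
        residual,
        x0=[0.05, 0.3, 0.02, 0.01, 0.02, 0.4, 1.1],
        bounds=(
            [0.0, 0.0, 0.0, 0.0, 0.001, 0.0, 0.5],
            [1.0, 1.0, 0.2, 0.2, 0.06, 1.0, 2.0],
        ),
        xtol=1e-14,
        ftol=1e-14,
    )
    fitted, crude, migfrac = unpack(sol.x)
    counts, cum, base_rates, births, migration = _baseline_run(
        initial, fitted, totals, crude, migfrac
    )
    demography = DemographySchedule(
        years=years,
        total_population=totals.to_numpy(),
        births=births,
        migration=migration,
        base_death_rate=base_rates,
        migration_fraction=migfrac,
    )

    dm = counts[:, _DM].sum(axis=1)
    first_year_incidence = cum[1] / counts[0, _NON_DM].sum()
    diagnostics = {
        "first_year_overall_incidence": float(first_year_incidence),
        "prevalence_2030_millions": float(dm[-1]),
        "prevalence_rate_2030": float(dm[-1] / counts[-1].sum()),
        "cumulative_incidence_2030_millions": float(cum[-1]),
        "max_population_target_rel_error": float(
            np.max(np.abs(counts.sum(axis=1) - totals.to_numpy()) / totals.to_numpy())
        ),
        "lsq_cost": float(sol.cost),
    }
    residuals = {"final": [float(v) for v in residual(sol.x)]}
    return CalibrationResult(
        params=fitted,
        demography=demography,
        initial=initial,
        crude_death_rate=crude,
        migration_fraction=migfrac,
        diagnosed_share_target=dtarget,
        residuals=residuals,
        diagnostics=diagnostics,
    )


def solve_incidence_growth(
    calibration: CalibrationResult, target_rate_increase_pp: float = 3.5
) -> float:
    """Annual incidence growth factor for the rising-incidence background.

    Solved so the no-intervention 2030 prevalence rate exceeds the flat-trend
    value by ``target_rate_increase_pp`` percentage points (default 3.5, the
    midpoint of the published "three to four" range).
    """
    flat = project(calibration.initial, calibration.params, calibration.demography)
    flat_rate = flat.prevalence_rate[-1]

    def gap(g):
        trial = calibration.params.with_(incidence_growth=float(g))
        res = project(calibration.initial, trial, calibration.demography)
        return (res.prevalence_rate[-1] - flat_rate) * 100.0 - target_rate_increase_pp

    return float(optimize.brentq(gap, 1.0, 1.08, xtol=1e-10))
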