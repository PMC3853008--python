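"""Transition-matrix construction and the annual difference equation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmpolicy import (
    DemographySchedule,
    EpidemiologicParameters,
    GlucoseState,
    StateVector,
    build_transition_matrix,
    cumulative_incidence_series,
    make_scenario,
    project,
    step,
)

ZERO_FLOW = EpidemiologicParameters(
    lambda_normal=0.0, lambda_ifg=0.0, lambda_ifgigt=0.0, detection_rate=0.0
)


def flat_schedule(start=2007, end=2010, total=100.0, base_rate=0.0):
    n = end - start + 1
    return DemographySchedule(
        years=np.arange(start, end + 1),
        total_population=np.full(n, total),
        births=np.zeros((n - 1, 5)),
        migration=np.zeros((n - 1, 5)),
        base_death_rate=np.full(n - 1, base_rate),
        migration_fraction=None,
    )


class TestBuildTransitionMatrix:
    def test_no_flows_and_no_deaths_gives_identity(self):
        m = build_transition_matrix(ZERO_FLOW, base_death_rate=0.0, year=2008)
        assert np.array_equal(m.p, np.eye(5))

    def test_diagnosed_row_sums_to_one_minus_rr_scaled_death(self):
        m = build_transition_matrix(ZERO_FLOW, base_death_rate=0.01, year=2008)
        assert m.p[GlucoseState.DIAG_DM].sum() == pytest.approx(1 - 0.0211)
        assert m.p[GlucoseState.UNDIAG_DM].sum() == pytest.approx(1 - 0.0177)

    def test_targeted_effectiveness_scales_incidence_outflow(self):
        params = EpidemiologicParameters()
        scen = make_scenario("moderate_risk", targeted_eff=0.125)
        m = build_transition_matrix(params, base_death_rate=0.0, scenario=scen, year=2008)
        row = m.p[GlucoseState.IFG_ONLY]
        dm_outflow = row[GlucoseState.UNDIAG_DM] + row[GlucoseState.DIAG_DM]
        assert dm_outflow == pytest.approx(0.024 * 0.875)

    def test_structural_zeros_and_row_sums(self, calib):
        m = build_transition_matrix(
            calib.params, base_death_rate=0.02, scenario=make_scenario("combined"), year=2010
        )
        m.validate()
        assert m.p[GlucoseState.DIAG_DM, GlucoseState.UNDIAG_DM] == 0
        assert np.all(m.p[3:, :3] == 0)

    def test_incidence_growth_compounds_from_reference_year(self):
        params = EpidemiologicParameters(incidence_growth=1.05)
        m0 = build_transition_matrix(params, 0.0, year=2008, growth_reference_year=2007)
        m5 = build_transition_matrix(params, 0.0, year=2013, growth_reference_year=2007)
        inc0 = m0.p[0, 3] + m0.p[0, 4]
        inc5 = m5.p[0, 3] + m5.p[0, 4]
        assert inc5 / inc0 == pytest.approx(1.05**5)

    def test_overspecified_outflow_raises(self):
        params = EpidemiologicParameters(detection_rate=0.9)
        with pytest.raises(ValueError, match="outflow"):
            build_transition_matrix(params, base_death_rate=0.2, year=2008)

    def test_targeting_a_diabetes_state_is_rejected(self):
        from dmpolicy.scenarios import InterventionScenario

        with pytest.raises(ValueError, match="cannot target"):
            InterventionScenario(
                "bad", 0.1, 0.0, (GlucoseState.DIAG_DM,)
            )


class TestStep:
    def test_identity_matrix_changes_only_year(self):
        sv = StateVector(2007, np.array([10.0, 5.0, 2.0, 1.0, 3.0]))
        m = build_transition_matrix(ZERO_FLOW, 0.0, year=2008)
        out = step(sv, m)
        assert out.year == 2008
        assert np.array_equal(out.counts, sv.counts)

    def test_hand_computed_matrix_vector_product(self):
        params = ZERO_FLOW.with_(prog_normal_to_ifg=0.1)
        m = build_transition_matrix(params, 0.0, year=2008)
        out = step(StateVector(2007, np.array([1.0, 0, 0, 0, 0])), m)
        assert out.counts == pytest.approx([0.9, 0.1, 0, 0, 0])

    def test_birth_vector_is_additive(self):
        sv = StateVector(2007, np.array([1.0, 1.0, 1.0, 1.0, 1.0]))
        m = build_transition_matrix(ZERO_FLOW, 0.0, year=2008)
        out = step(sv, m, births=np.ones(5))
        assert out.counts == pytest.approx(sv.counts + 1)

    def test_year_mismatch_raises(self):
        sv = StateVector(2006, np.ones(5))
        m = build_transition_matrix(ZERO_FLOW, 0.0, year=2008)
        with pytest.raises(ValueError, match="transition into"):
            step(sv, m)

    def test_negative_result_signals_inconsistent_demography(self):
        sv = StateVector(2007, np.ones(5))
        m = build_transition_matrix(ZERO_FLOW, 0.0, year=2008)
        with pytest.raises(ValueError, match="negative population"):
            step(sv, m, migration=-2 * np.ones(5))


@st.composite
def small_params(draw):
    lam_n = draw(st.floats(0.001, 0.004))
    lam_ifg = draw(st.floats(0.01, 0.03))
    lam_igt = draw(st.floats(0.031, 0.06))
    return EpidemiologicParameters(
        lambda_normal=lam_n,
        lambda_ifg=lam_ifg,
        lambda_ifgigt=lam_igt,
        detection_rate=draw(st.floats(0.0, 0.3)),
        diagnosed_at_onset_fraction=draw(st.floats(0.0, 1.0)),
        prog_normal_to_ifg=draw(st.floats(0.0, 0.05)),
        prog_ifg_to_ifgigt=draw(st.floats(0.0, 0.05)),
    )


class TestProject:
    def test_three_year_run_equals_hand_unrolled_matrix_products(self):
        rng = np.random.default_rng(7)
        params = EpidemiologicParameters(
            detection_rate=0.1,
            diagnosed_at_onset_fraction=0.4,
            prog_normal_to_ifg=0.02,
            prog_ifg_to_ifgigt=0.01,
        )
        n = len(np.arange(2007, 2011))
        births = rng.uniform(0, 1, (n - 1, 5))
        migration = rng.uniform(0, 0.5, (n - 1, 5))
        base = np.array([0.01, 0.012, 0.011])
        dem = DemographySchedule(
            years=np.arange(2007, 2011),
            total_population=np.full(n, 100.0),  # unused: entrants stored
            births=births,
            migration=migration,
            base_death_rate=base,
            migration_fraction=None,
        )
        initial = StateVector(2007, np.array([60.0, 18.0, 8.0, 4.0, 10.0]))
        res = project(initial, params, dem, end_year=2010)

        # Independent unrolled recursion.
        x = initial.counts.copy()
        for k, year in enumerate([2008, 2009, 2010]):
            p = build_transition_matrix(
                params, base[k], year=year, growth_reference_year=2007
            ).p
            x = x @ p + births[k] + migration[k]
        assert res.at(2010).counts == pytest.approx(x, rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(params=small_params(), base=st.floats(0.0, 0.02))
    def test_population_conservation_each_year(self, params, base):
        """total(N(t)) == total(N(t-1)) - deaths + births + migration, to 1e-9."""
        dem = flat_schedule(2007, 2012, base_rate=base)
        dem.births[:, 0] = 1.0
        dem.migration[:, :] = 0.1
        initial = StateVector(2007, np.array([60.0, 18.0, 8.0, 4.0, 10.0]))
        res = project(initial, params, dem)
        for i in range(1, len(res.states)):
            lhs = res.states[i].total
            rhs = (
                res.states[i - 1].total
                - res.deaths[i].sum()
                + dem.births[i - 1].sum()
                + dem.migration[i - 1].sum()
            )
            assert lhs == pytest.approx(rhs, rel=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(params=small_params())
    def test_diagnosed_diabetes_absorbing_without_mortality(self, params):
        dem = flat_schedule(2007, 2015, base_rate=0.0)
        initial = StateVector(2007, np.array([60.0, 18.0, 8.0, 4.0, 10.0]))
        res = project(initial, params, dem)
        diag = res.counts[:, GlucoseState.DIAG_DM]
        assert np.all(np.diff(diag) >= -1e-12)

    def test_zero_incidence_run_accumulates_nothing(self):
        dem = flat_schedule()
        initial = StateVector(2007, np.array([60.0, 18.0, 8.0, 4.0, 10.0]))
        res = project(initial, ZERO_FLOW, dem)
        assert np.all(res.cumulative_incidence == 0)

    def test_zero_effectiveness_scenario_equals_no_intervention(self, calib):
        null = make_scenario("moderate_risk", targeted_eff=0.0, population_eff=0.0)
        a = project(calib.initial, calib.params, calib.demography)
        b = project(calib.initial, calib.params, calib.demography, scenario=null)
        assert a.counts == pytest.approx(b.counts, rel=1e-14)

    def test_cumulative_series_differences_match_direct_inflows(self, calib, base_runs):
        res = base_runs["none"]
        series = cumulative_incidence_series(res)
        assert np.all(np.diff(series.to_numpy()) > 0)
        # recompute each year's inflow directly from N(t-1) . P(t) columns
        for k in (1, 10, 23):
            year = int(res.years[k])
            matrix = build_transition_matrix(
                calib.params,
                base_death_rate=float(calib.demography.base_death_rate[k - 1]),
                year=year,
                growth_reference_year=2007,
            )
            prev = res.states[k - 1].counts
            inflow = prev[:3] @ matrix.p[:3, 3:].sum(axis=1)
            assert series.iloc[k] - series.iloc[k - 1] == pytest.approx(inflow, rel=1e-12)

    def test_horizon_not_covered_raises(self, calib):
        with pytest.raises(ValueError, match="does not cover"):
            project(calib.initial, calib.params, calib.demography, end_year=2050)
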