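"""Care stocks and visit demand: flows, balance, initialization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eyeforce import care_demand as cd
from eyeforce.calibration import UptakeDemandSimulator
from eyeforce.dimensions import (
    CARE_SHAPE,
    CONDITION_INDEX,
    EDUCATIONS,
    N_ADULT_AGES,
)

CAT = CONDITION_INDEX["cataract"]
GLA = CONDITION_INDEX["glaucoma"]
MYO = CONDITION_INDEX["myopia"]


def empty_state(year: float = 2010.0) -> cd.CareState:
    return cd.CareState(year, np.zeros(CARE_SHAPE), np.zeros(CARE_SHAPE))


class TestUntreatedPool:
    def test_empty_stocks_pool_equals_prevalent(self):
        prevalent = np.full(CARE_SHAPE, 7.0)
        pool = cd.untreated_pool(prevalent, empty_state())
        assert np.array_equal(pool, prevalent)

    def test_subtraction_arithmetic(self):
        prevalent = np.zeros(CARE_SHAPE)
        prevalent[CAT, 10, 1] = 1000.0
        state = empty_state()
        state.in_care[CAT, 10, 1] = 300.0
        state.completed[CAT, 10, 1] = 100.0
        assert cd.untreated_pool(prevalent, state)[CAT, 10, 1] == pytest.approx(600.0)

    def test_clamped_at_zero_when_in_care_exceeds_prevalent(self):
        prevalent = np.zeros(CARE_SHAPE)
        prevalent[GLA, 5, 0] = 50.0
        state = empty_state()
        state.in_care[GLA, 5, 0] = 80.0   # uptake absorbs foreigners/under-40s
        pool = cd.untreated_pool(prevalent, state)
        assert pool[GLA, 5, 0] == 0.0
        assert (pool >= 0).all()


class TestNewPatientFlow:
    def test_uptake_times_pool(self):
        untreated = np.zeros(CARE_SHAPE)
        untreated[GLA, 10, EDUCATIONS.index("primary")] = 1000.0
        flow = cd.new_patient_flow(untreated, cd.CareParameters(), 2010)
        assert flow.sum() == pytest.approx(70.0)   # baseline primary uptake 0.07

    def test_zero_uptake_zero_flow(self):
        params = cd.CareParameters(uptake={e: 0.0 for e in EDUCATIONS})
        flow = cd.new_patient_flow(np.full(CARE_SHAPE, 5.0), params, 2010)
        assert flow.sum() == 0.0

    def test_mixed_education_pool(self):
        untreated = np.zeros(CARE_SHAPE)
        untreated[GLA, 10, EDUCATIONS.index("none")] = 500.0
        untreated[GLA, 10, EDUCATIONS.index("tertiary")] = 200.0
        flow = cd.new_patient_flow(untreated, cd.CareParameters(), 2010)
        assert flow.sum() == pytest.approx(500 * 0.045 + 200 * 0.15)  # 52.5

    def test_rejects_uptake_outside_unit_interval(self):
        params = cd.CareParameters(uptake={e: 1.5 for e in EDUCATIONS})
        with pytest.raises(ValueError):
            cd.new_patient_flow(np.zeros(CARE_SHAPE), params, 2010)


class TestSplitDecant:
    def test_new_model_myopia_split(self):
        new = np.zeros(CARE_SHAPE)
        new[MYO, 3, 2] = 100.0
        params = cd.CareParameters(decant_fraction={"myopia": 0.90})
        soc, pec = cd.split_decant(new, params, 2020)
        assert soc[MYO, 3, 2] == pytest.approx(10.0)
        assert pec[MYO, 3, 2] == pytest.approx(90.0)

    def test_baseline_dr_split(self):
        new = np.zeros(CARE_SHAPE)
        new[CONDITION_INDEX["dr"], 3, 2] = 100.0
        params = cd.CareParameters(decant_fraction={"dr": 0.05})
        soc, _ = cd.split_decant(new, params, 2020)
        assert soc[CONDITION_INDEX["dr"], 3, 2] == pytest.approx(95.0)

    def test_undecanted_condition_passes_through(self):
        new = np.zeros(CARE_SHAPE)
        new[CAT, 3, 2] = 100.0
        soc, pec = cd.split_decant(new, cd.CareParameters(), 2020)
        assert soc[CAT, 3, 2] == 100.0
        assert pec.sum() == 0.0

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1e6))
    def test_complementarity(self, fraction, volume):
        new = np.full(CARE_SHAPE, volume)
        params = cd.CareParameters(decant_fraction={"myopia": fraction, "dr": fraction})
        soc, pec = cd.split_decant(new, params, 2020)
        # the specialist flow is defined as the exact residual of the split
        assert np.array_equal(soc, new - pec)
        assert np.allclose(soc + pec, new, rtol=1e-12)


class TestCompletionFlow:
    def test_cataract_three_year_course(self):
        state = empty_state()
        state.in_care[CAT, 7, 1] = 300.0
        flow = cd.completion_flow(state, cd.CareParameters())
        assert flow[CAT, 7, 1] == pytest.approx(100.0)

    def test_lifelong_conditions_never_complete(self):
        state = empty_state()
        state.in_care[GLA, 7, 1] = 300.0
        assert cd.completion_flow(state, cd.CareParameters()).sum() == 0.0

    def test_myopia_one_year_course(self):
        state = empty_state()
        state.in_care[MYO, 7, 1] = 50.0
        flow = cd.completion_flow(state, cd.CareParameters())
        assert flow[MYO, 7, 1] == pytest.approx(50.0)


class TestStepCare:
    def test_zero_flows_zero_mortality_only_ages(self):
        state = empty_state()
        state.in_care[GLA, 7, 1] = 40.0
        zero = np.zeros(CARE_SHAPE)
        new = cd.step_care(state, zero, zero, np.zeros(N_ADULT_AGES), dt=1.0)
        assert new.in_care[GLA, 8, 1] == 40.0
        assert new.in_care.sum() == 40.0

    def test_single_cohort_hand_balance(self):
        # stock 90, inflow 100/yr, completion rate 1/3, mortality 0.01, dt=1:
        # completion 30, deaths 0.9 -> 90 + (100 - 30 - 0.9) = 159.1, aged one bin;
        # completed gains the 30 completers.
        state = empty_state()
        state.in_care[CAT, 10, 1] = 90.0
        inflow = np.zeros(CARE_SHAPE)
        inflow[CAT, 10, 1] = 100.0
        completion = cd.completion_flow(state, cd.CareParameters())
        mu = np.full(N_ADULT_AGES, 0.01)
        new, audit = cd.step_care(state, inflow, completion, mu, dt=1.0,
                                  return_audit=True)
        assert new.in_care[CAT, 11, 1] == pytest.approx(159.1)
        assert new.completed[CAT, 11, 1] == pytest.approx(30.0 * (1 - 0.0))
        assert audit.imbalance < 1e-12

    def test_curable_stock_converges_to_inflow_times_duration(self):
        """Constant inflow F with duration D settles at F*D (zero mortality)."""
        state = empty_state()
        inflow = np.zeros(CARE_SHAPE)
        inflow[CAT, 0, 1] = 30.0
        params = cd.CareParameters()
        mu = np.zeros(N_ADULT_AGES)
        for _ in range(30 * 4):
            completion = cd.completion_flow(state, params)
            state = cd.step_care(state, inflow, completion, mu, dt=0.25)
        assert state.in_care.sum() == pytest.approx(90.0, rel=0.01)

    # dt restricted so (completion + mortality) * dt < 1 — the explicit-Euler
    # stability regime the integrator runs in (package default dt = 0.25).
    @given(st.floats(0.0, 0.3), st.floats(0.0, 200.0),
           st.sampled_from([0.25, 0.5]))
    def test_stock_balance_audit(self, mortality, inflow_level, dt):
        state = empty_state()
        state.in_care += 25.0
        inflow = np.full(CARE_SHAPE, inflow_level)
        completion = cd.completion_flow(state, cd.CareParameters())
        mu = np.full(N_ADULT_AGES, mortality)
        _, audit = cd.step_care(state, inflow, completion, mu, dt, return_audit=True)
        assert audit.imbalance < 1e-9


class TestDemandVisits:
    def test_visit_rate_arithmetic(self):
        state = empty_state()
        state.in_care[GLA, 7, 1] = 1000.0
        total, _ = cd.demand_visits(state, cd.CareParameters())
        assert total == pytest.approx(2400.0)

    def test_empty_care_zero_demand(self):
        total, by_cond = cd.demand_visits(empty_state(), cd.CareParameters())
        assert total == 0.0
        assert by_cond.sum() == 0.0

    def test_per_condition_additivity(self):
        rng = np.random.default_rng(0)
        state = cd.CareState(2010, rng.uniform(0, 10, CARE_SHAPE),
                             np.zeros(CARE_SHAPE))
        total, by_cond = cd.demand_visits(state, cd.CareParameters())
        assert total == pytest.approx(by_cond.sum(), rel=1e-12)


class TestInitializeCareState:
    def test_base_demand_to_patients(self):
        prevalent = np.full(CARE_SHAPE, 100.0)
        state = cd.initialize_care_state(568_200.0, cd.CareParameters(),
                                         prevalent, 2010)
        assert state.patients() == pytest.approx(568_200.0 / 2.4)   # 236 750
        cataract_share = state.in_care[CAT].sum() / state.patients()
        assert cataract_share == pytest.approx(0.31)

    def test_completed_seeded_at_fraction_of_in_care(self):
        prevalent = np.full(CARE_SHAPE, 100.0)
        state = cd.initialize_care_state(240_000.0, cd.CareParameters(),
                                         prevalent, 2010)
        for name in ("cataract", "myopia", "refractive_error"):
            i = CONDITION_INDEX[name]
            assert state.completed[i].sum() == pytest.approx(
                0.1 * state.in_care[i].sum())
        assert state.completed[GLA].sum() == 0.0

    def test_empty_stratum_receives_no_patients(self):
        prevalent = np.full(CARE_SHAPE, 100.0)
        prevalent[:, :, 3] = 0.0
        state = cd.initialize_care_state(240_000.0, cd.CareParameters(),
                                         prevalent, 2010)
        assert state.in_care[:, :, 3].sum() == 0.0

    def test_rejects_bad_case_mix(self):
        mix = dict(cd.DEFAULT_CASE_MIX)
        mix["other"] = 0.5
        with pytest.raises(ValueError):
            cd.CareParameters(case_mix=mix)


class TestEquilibriumState:
    def test_equilibrium_is_stationary_between_shifts(self):
        rng = np.random.default_rng(3)
        prevalent = rng.uniform(50, 150, CARE_SHAPE)
        params = cd.CareParameters()
        mu = np.linspace(0.005, 0.3, N_ADULT_AGES)
        state = cd.equilibrium_care_state(prevalent, params, mu, 2010)
        untreated = cd.untreated_pool(prevalent, state)
        inflow = cd.new_patient_flow(untreated, params, 2010)
        completion = cd.completion_flow(state, params)
        new = cd.step_care(state, inflow, completion, mu, dt=0.25)
        assert np.allclose(new.in_care, state.in_care, rtol=1e-9)
        assert np.allclose(new.completed, state.completed, rtol=1e-9)


class TestMonotoneUptakeResponse:
    def test_raising_uptake_never_decreases_demand(self, world):
        years = list(range(2010, 2021))
        sim = UptakeDemandSimulator(world, years,
                                    population_trajectory=world.population_trajectory(2020))
        base = np.array([world.true_uptake[e] for e in EDUCATIONS])
        low = sim.series(base)["total"].to_numpy()
        high = sim.series(base * 1.2)["total"].to_numpy()
        assert (high >= low - 1e-9).all()
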