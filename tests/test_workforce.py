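"""Training pipeline dynamics, requirement conversion, intake planning."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eyeforce import workforce as wf
from eyeforce.timeseries import YearPath


def simple_rates(**kw) -> wf.PipelineRates:
    defaults = dict(
        admissions=YearPath.constant(100.0),
        desired_medical_officers=YearPath.constant(0.0),
        mo_attrition=YearPath.constant(0.1),
    )
    defaults.update(kw)
    return wf.PipelineRates(**defaults)


def flat_workload(ratio: float = 5000.0, multiplier: float = 1.0) -> wf.WorkloadModel:
    return wf.WorkloadModel(intercept=ratio, slope=0.0, last_data_year=2014,
                            workload_multiplier=multiplier)


class TestRequiredOphthalmologists:
    def test_demand_over_workload(self):
        cont, rep = wf.required_ophthalmologists(1_200_000.0, flat_workload(), 2020)
        assert cont == pytest.approx(240.0)
        assert rep == 240

    def test_moderated_workload_raises_requirement(self):
        _, rep = wf.required_ophthalmologists(
            1_200_000.0, flat_workload(multiplier=0.85), 2020)
        assert rep == math.ceil(240.0 / 0.85)   # 283

    def test_zero_demand_zero_requirement(self):
        cont, rep = wf.required_ophthalmologists(0.0, flat_workload(), 2020)
        assert cont == 0.0 and rep == 0

    def test_workload_fit_and_constant_extrapolation(self):
        years = np.arange(2003, 2015)
        series = 6000.0 - 80.0 * (years - 2003)
        model = wf.fit_workload(years, series)
        assert model.workload(2010) == pytest.approx(6000.0 - 80.0 * 7, rel=1e-9)
        # beyond the data the fitted 2014 value is held
        assert model.workload(2040) == pytest.approx(model.workload(2014))

    @given(st.floats(1e3, 1e7))
    def test_multiplier_scaling_law(self, demand):
        full, _ = wf.required_ophthalmologists(demand, flat_workload(), 2020)
        moderated, _ = wf.required_ophthalmologists(
            demand, flat_workload(multiplier=0.85), 2020)
        assert moderated == pytest.approx(full / 0.85, rel=1e-12)


class TestDesiredHiring:
    def test_gap_plus_expected_attrition(self):
        assert wf.desired_hiring(310.0, 300.0, 0.03) == pytest.approx(19.0)

    def test_no_gap_no_attrition_no_hiring(self):
        assert wf.desired_hiring(300.0, 300.0, 0.0) == 0.0

    def test_clamped_at_zero(self):
        assert wf.desired_hiring(295.0, 300.0, 0.01) == 0.0


class TestStepPipeline:
    def test_zero_intake_zero_attrition_constant_stock(self):
        rates = simple_rates(residency_intake=YearPath.constant(0.0),
                             oph_attrition=0.0)
        state = wf.WorkforceState(2010.0, 500.0, 100.0, 0.0,
                                  np.zeros(5), 200.0)
        for _ in range(12):
            state = wf.step_pipeline(state, rates, hires_demanded=10.0, dt=0.25)
        assert state.ophthalmologists == 200.0

    def test_no_supply_response_before_residency_delay(self):
        """A pulse of intake produces graduates exactly 5 years later."""
        pulse = lambda year: 5.0 if 2010 <= year < 2011 else 0.0
        rates = simple_rates(residency_intake=pulse, oph_attrition=0.0)
        state = wf.WorkforceState(2010.0, 500.0, 100.0, 0.0, np.zeros(5), 50.0)
        supply = {}
        for _ in range(4 * 7):
            state = wf.step_pipeline(state, rates, hires_demanded=1e9, dt=0.25)
            supply[state.year] = state.ophthalmologists
        assert all(v == 50.0 for t, v in supply.items() if t < 2015)
        assert supply[2015.0] == pytest.approx(55.0)

    def test_steady_state_supply_is_intake_over_attrition(self):
        """Constant intake 9/yr, attrition 3%/yr: supply -> ~9/0.03 = 300."""
        rates = simple_rates(residency_intake=YearPath.constant(9.0))
        state = wf.steady_pipeline_state(rates, 2000.0, ophthalmologists=0.0)
        for _ in range(150 * 4):
            state = wf.step_pipeline(state, rates, hires_demanded=1e9, dt=0.25)
        assert state.ophthalmologists == pytest.approx(300.0, rel=0.02)

    def test_conservation_audit(self):
        rates = simple_rates(desired_medical_officers=YearPath.constant(40.0))
        state = wf.steady_pipeline_state(rates, 2010.0, ophthalmologists=100.0)
        for _ in range(40):
            state, audit = wf.step_pipeline(state, rates, hires_demanded=3.0,
                                            dt=0.25, return_audit=True)
            assert audit.imbalance < 1e-9

    def test_supply_monotone_in_intake(self):
        required = np.linspace(100, 250, 30)
        for k in range(0, 20, 3):
            lo = wf.simulate_supply(100.0, simple_rates(), k, required)
            hi = wf.simulate_supply(100.0, simple_rates(), k + 1, required)
            assert (hi >= lo - 1e-12).all()


class TestPlanRequiredIntake:
    def test_static_requirement_zero_attrition_needs_no_intake(self):
        rates = simple_rates(oph_attrition=0.0)
        required = np.full(20, 150.0)
        lo, hi = wf.plan_required_intake([required, required], rates,
                                         initial_supply=150.0)
        assert (lo, hi) == (0, 0)

    def test_matches_exhaustive_scan_on_synthetic_cases(self):
        """Bisection result equals a brute-force scan over intakes 0..60."""
        cases = [
            (100.0, np.linspace(100, 280, 30), 0.03),
            (100.0, np.linspace(100, 250, 25), 0.00),
            (50.0, np.linspace(60, 200, 30), 0.05),
            (200.0, np.linspace(210, 300, 35), 0.03),
            (80.0, 80.0 + 6.0 * np.arange(30), 0.03),
        ]
        for initial, required, attrition in cases:
            rates = simple_rates(oph_attrition=attrition)
            slack = 0.1 * float(np.max(required))
            scan = next(
                k for k in range(0, 61)
                if wf._intake_meets(k, initial, rates, required, slack)
            )
            lo, hi = wf.plan_required_intake([required], rates, initial,
                                             bounds=(0, 60))
            assert lo == hi == scan

    def test_interval_shape_lower_below_upper(self):
        rates = simple_rates()
        low_traj = np.linspace(100, 180, 30)
        high_traj = np.linspace(100, 320, 30)
        lo, hi = wf.plan_required_intake([low_traj, high_traj], rates, 100.0)
        assert lo <= hi
        assert isinstance(lo, int) and isinstance(hi, int)

    def test_infeasible_raises_diagnostic(self):
        rates = simple_rates(oph_attrition=0.9)
        required = np.linspace(100, 5000, 30)
        with pytest.raises(wf.InfeasibleIntakeError):
            wf.plan_required_intake([required], rates, 10.0, bounds=(0, 5))

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            wf.plan_required_intake([np.array([1.0, 2.0])], simple_rates(), 10.0)
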