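"""Cohort-component projection: flows, aging, conservation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eyeforce import demography as dg
from eyeforce.dimensions import EDUCATION_INDEX, N_AGES, OPEN_AGE

from conftest import make_inputs, toy_state

NONE = EDUCATION_INDEX["none"]


class TestBirthFlow:
    def test_zero_rate_gives_zero_newborns(self):
        state = toy_state({(30, 0, 0, 2): 10_000.0})
        births = dg.birth_flow(state, make_inputs(birth_rate=0.0), 2010)
        assert births.sum() == 0.0

    def test_reproductive_age_arithmetic(self):
        # 10 000 reproductive-age Chinese females, rate 0.05, split half female.
        state = toy_state({(20, 0, 0, 2): 4_000.0, (35, 0, 0, 2): 6_000.0,
                           (60, 0, 0, 2): 5_000.0})   # 60-year-olds don't count
        births = dg.birth_flow(state, make_inputs(birth_rate=0.05), 2010)
        assert births.sum() == pytest.approx(500.0)
        assert births[0, 0] == pytest.approx(250.0)   # female newborns, Chinese

    def test_males_do_not_contribute(self):
        state = toy_state({(30, 1, 0, 2): 10_000.0})
        births = dg.birth_flow(state, make_inputs(birth_rate=0.05), 2010)
        assert births.sum() == 0.0


class TestMigrationFlow:
    def test_on_target_gives_zero(self):
        state = toy_state({(30, 0, 0, 0): 1000.0})
        inputs = make_inputs(target=1000.0, fraction_immigrating=0.3)
        assert dg.migration_flow(state, inputs, 2010).sum() == pytest.approx(0.0)

    def test_gap_closure_rate(self):
        state = toy_state({(30, 0, 0, 0): 50_000.0})
        inputs = make_inputs(target=150_000.0, fraction_immigrating=0.3)
        assert dg.migration_flow(state, inputs, 2010).sum() == pytest.approx(30_000.0)

    def test_emigration_proportional_to_counts(self):
        state = toy_state({(30, 0, 0, 0): 60_000.0, (40, 1, 1, 1): 40_000.0})
        inputs = make_inputs(target=50_000.0, fraction_immigrating=0.3)
        flow = dg.migration_flow(state, inputs, 2010)
        assert flow.sum() == pytest.approx(-15_000.0)
        assert flow[30, 0, 0, 0] == pytest.approx(-15_000.0 * 0.6)
        assert flow[40, 1, 1, 1] == pytest.approx(-15_000.0 * 0.4)


class TestStepPopulation:
    def test_three_cohort_toy_hand_oracle(self):
        # counts 100/50/0 at ages 0/1/2, death rate 0.1, one 1-year step:
        # deaths 15, survivors shift to [0, 90, 45].
        state = toy_state({(0, 0, 0, NONE): 100.0, (1, 0, 0, NONE): 50.0})
        inputs = make_inputs(death_rate=0.1)
        new, audit = dg.step_population(state, inputs, dt=1.0, return_audit=True)
        assert audit.deaths * audit.dt == pytest.approx(15.0)
        assert new.counts[0].sum() == 0.0
        assert new.counts[1, 0, 0, NONE] == pytest.approx(90.0)
        assert new.counts[2, 0, 0, NONE] == pytest.approx(45.0)

    def test_closed_population_total_exactly_constant(self):
        state = toy_state({(a, 0, 0, 1): 100.0 for a in range(30, 60)})
        inputs = make_inputs()
        traj = dg.project_population(inputs, state, 2015)
        assert all(s.total() == state.total() for s in traj)

    def test_pure_aging_shifts_mean_age(self):
        state = toy_state({(a, 0, 0, 1): 100.0 for a in range(30, 60)})
        traj = dg.project_population(make_inputs(), state, 2015)
        assert traj[-1].mean_age() == pytest.approx(state.mean_age() + 5.0)

    def test_open_age_bin_absorbs(self):
        state = toy_state({(99, 0, 0, 1): 10.0, (OPEN_AGE, 0, 0, 1): 5.0})
        new = dg.step_population(state, make_inputs(), dt=1.0)
        assert new.counts[OPEN_AGE, 0, 0, 1] == pytest.approx(15.0)

    def test_rejects_bad_dt(self):
        state = toy_state({(30, 0, 0, 1): 10.0})
        with pytest.raises(ValueError):
            dg.step_population(state, make_inputs(), dt=0.0)

    def test_education_assignment_preserves_totals(self):
        dist = np.array([0.1, 0.2, 0.3, 0.4])
        inputs = make_inputs(education_assignment=lambda year: dist)
        state = toy_state({(24, 0, 0, NONE): 1000.0})
        new = dg.step_population(state, inputs, dt=1.0)
        assert new.total() == pytest.approx(1000.0)
        assert np.allclose(new.counts[25, 0, 0], 1000.0 * dist)


class TestProjectPopulation:
    def test_identity_at_zero_horizon(self):
        state = toy_state({(30, 0, 0, 1): 10.0})
        traj = dg.project_population(make_inputs(), state, 2010)
        assert len(traj) == 1
        assert np.array_equal(traj[0].counts, state.counts)

    def test_composition_of_single_steps(self):
        state = toy_state({(a, 0, 1, 2): 50.0 + a for a in range(20, 40)})
        inputs = make_inputs(birth_rate=0.02, death_rate=0.01,
                             target=30_000.0, fraction_immigrating=0.2)
        traj = dg.project_population(inputs, state, 2013, dt=0.25)
        manual = state.copy()
        for _ in range(12):
            manual = dg.step_population(manual, inputs, 0.25)
        assert np.array_equal(traj[-1].counts, manual.counts)

    def test_matches_independent_cohort_loop(self):
        """5-cohort model vs a hand-rolled pure-python loop, 30 annual steps."""
        ages = list(range(5))
        start = {a: 1000.0 - 50.0 * a for a in ages}
        death = np.zeros(N_AGES)
        for a in range(N_AGES):
            death[a] = min(0.01 + 0.001 * a, 0.9)

        state = toy_state({(a, 0, 0, 0): v for a, v in start.items()})
        inputs = make_inputs(death_rate=death)
        traj = dg.project_population(inputs, state, 2040, dt=1.0)

        # independent oracle: plain dict-based cohort bookkeeping
        cohorts = dict(start)
        for _ in range(30):
            survived = {a: v * (1.0 - death[a]) for a, v in cohorts.items()}
            cohorts = {a + 1: v for a, v in survived.items()}
        result = traj[-1].counts[:, 0, 0, 0]
        for a, v in cohorts.items():
            assert result[a] == pytest.approx(v, abs=1e-9)
        assert traj[-1].total() == pytest.approx(sum(cohorts.values()), abs=1e-9)


class TestConservation:
    @given(
        death=st.floats(0.0, 0.5),
        birth=st.floats(0.0, 0.05),
        dt=st.sampled_from([0.25, 0.5, 1.0]),
        gap=st.floats(0.0, 50_000.0),
    )
    def test_step_balance_and_nonnegativity(self, death, birth, dt, gap):
        state = toy_state({(a, g, 0, 1): 500.0 for a in range(20, 70) for g in (0, 1)})
        inputs = make_inputs(birth_rate=birth, death_rate=death,
                             target=state.total() + gap, fraction_immigrating=0.3)
        new, audit = dg.step_population(state, inputs, dt, return_audit=True)
        assert audit.imbalance < 1e-9
        assert (new.counts >= 0).all()

    def test_projection_tracks_national_target(self, world):
        traj = world.population_trajectory(2040)
        target = world.scale * 6.9 / 5.4
        assert abs(traj[-1].total() - target) / target < 0.01
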