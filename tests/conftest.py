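"""Shared fixtures: one synthetic world and its scenario/calibration products.

Session scope keeps the heavier artefacts (scenario bundle, posterior
chain) computed once and reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import eyeforce as ef
from eyeforce import calibration as cal
from eyeforce import demography as dg
from eyeforce import scenarios as sc
from eyeforce.dimensions import EDUCATIONS, N_AGES, N_ETHNICITIES, POP_SHAPE
from eyeforce.timeseries import TimeTable, YearPath

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

WORLD_SEED = 1


@pytest.fixture(scope="session")
def world():
    return ef.generate_world(WORLD_SEED)


@pytest.fixture(scope="session")
def stress_world():
    return ef.synthetic_data.generate_aging_stress_world(WORLD_SEED)


@pytest.fixture(scope="session")
def scenario_runs(world):
    return sc.run_all_scenarios(world, collect_audits=True)


@pytest.fixture(scope="session")
def posterior(world):
    """Calibration problem, fast simulator and a converged chain."""
    problem = cal.CalibrationProblem(
        world.observed_history[list(EDUCATIONS)], noise_sd=world.noise_sd)
    sim = cal.UptakeDemandSimulator(
        world, world.observed_history.index,
        population_trajectory=world.population_trajectory(2020))
    sample = cal.run_mcmc(problem, sim, n_iterations=1500, seed=7)
    return problem, sim, sample


def make_inputs(
    birth_rate: float = 0.0,
    death_rate: float | np.ndarray = 0.0,
    target: float | None = None,
    fraction_immigrating: float = 0.0,
    **kwargs,
) -> dg.DemographicInputs:
    """Minimal demographic inputs for toy models."""
    years = np.array([2010.0])
    death = np.full(N_AGES, death_rate) if np.isscalar(death_rate) else death_rate
    profile = np.full(POP_SHAPE, 1.0 / np.prod(POP_SHAPE))
    return dg.DemographicInputs(
        birth_rate=TimeTable(years, np.full((N_ETHNICITIES, 1), birth_rate)),
        death_rate=TimeTable(years, np.asarray(death, dtype=float)[:, None]),
        desired_total_population=YearPath.constant(0.0 if target is None else target),
        migrant_age_profile=profile,
        fraction_immigrating=fraction_immigrating,
        **kwargs,
    )


def toy_state(cells: dict[tuple[int, int, int, int], float],
              year: float = 2010.0) -> dg.PopulationState:
    """Population state with counts only in the listed (age, g, e, d) cells."""
    counts = np.zeros(POP_SHAPE)
    for idx, value in cells.items():
        counts[idx] = value
    return dg.PopulationState(year, counts)
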