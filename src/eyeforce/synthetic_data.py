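"""Synthetic model inputs with known ground truth.

Every input the projection pipeline needs — a base population with a
realistic age pyramid, vital-rate series, age-increasing prevalence
proportions for the nine conditions, a case mix, a historical workload
series and a noisy observed visit history generated from known "true"
uptake factors — is produced here from a seed, so every stage of the
package is testable end to end without any external data.

The generated world emulates the *statistical structure* of the source
setting (an aging Southeast-Asian city-state population steered toward a
national population target, SEED-style prevalence rising with age with
myopia most and retinal vein occlusion least prevalent, an administrative
case mix over nine conditions) at a configurable scale, default 500 000
residents, roughly a tenth of the real resident population; all
downstream acceptance properties are scale-free.  Regenerating with the
same seed reproduces every field bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import care_demand as cd
from . import demography as dg
from . import prevalence as pv
from . import workforce as wf
from .calibration import UptakeDemandSimulator
from .dimensions import (
    ADULT_MIN_AGE,
    CONDITIONS,
    CONDITION_INDEX,
    EDUCATIONS,
    ETHNICITIES,
    N_AGES,
    N_EDUCATIONS,
    POP_SHAPE,
)
from .timeseries import TimeTable, YearPath

__all__ = [
    "SyntheticWorld",
    "generate_world",
    "generate_aging_stress_world",
    "flatten_prevalence",
    "demand_vs_population_growth",
]

BASE_YEAR = 2010
HORIZON = 2040
REAL_RESIDENT_POPULATION = 5.4e6     # reference scale of the emulated setting
NATIONAL_TARGET = 6.9e6              # national population target at the horizon

_ETHNIC_SHARES = np.array([0.74, 0.13, 0.09, 0.04])

# Logistic-in-age prevalence: condition -> (plateau, inflection age, scale yrs).
_PREVALENCE_SHAPES = {
    "cataract": (0.92, 72.0, 8.0),
    "dr": (0.12, 68.0, 12.0),
    "glaucoma": (0.10, 78.0, 10.0),
    "amd": (0.28, 80.0, 8.0),
    "myopia": (0.58, 30.0, 25.0),
    "refractive_error": (0.22, 55.0, 15.0),
    "erm": (0.38, 75.0, 9.0),
    "rvo": (0.025, 80.0, 10.0),
    "other": (0.10, 75.0, 12.0),
}

# Mild ethnicity gradients; diabetic retinopathy is raised in the Malay and
# Indian strata, myopia in the Chinese stratum.
_ETHNICITY_MULT = {
    "default": np.array([1.0, 1.05, 1.10, 0.95]),
    "dr": np.array([1.0, 1.35, 1.40, 1.0]),
    "myopia": np.array([1.10, 0.80, 0.90, 1.0]),
}
# Lower educational attainment carries higher prevalence, except myopia.
_EDUCATION_MULT = {
    "default": np.array([1.15, 1.05, 0.95, 0.85]),
    "myopia": np.array([0.80, 0.90, 1.05, 1.25]),
}

_YOUNG_EDU = np.array([0.03, 0.10, 0.42, 0.45])   # education mix at labour entry, 2010
_OLD_EDU = np.array([0.30, 0.35, 0.25, 0.10])     # education mix of the oldest cohorts
_EDU_2040 = np.array([0.02, 0.08, 0.35, 0.55])    # labour-entry mix by 2040

#: Fraction of the prevalent 40+ pool in specialist care in the base year;
#: sets the administrative starting demand.
BASE_IN_CARE_FRACTION = 0.10


@dataclass
class SyntheticWorld:
    """A complete, internally consistent set of model inputs."""

    seed: int
    scale: float
    base_year: int
    base_population: dg.PopulationState
    demographic_inputs: dg.DemographicInputs
    prevalence_table: pv.PrevalenceTable
    care_params: cd.CareParameters
    pipeline_rates: wf.PipelineRates
    workload_series: pd.Series
    workload_model: wf.WorkloadModel
    true_uptake: dict[str, float]
    base_demand_visits: float
    observed_history: pd.DataFrame
    noise_sd: float
    _trajectories: dict = field(default_factory=dict, repr=False, compare=False)

    def population_trajectory(self, horizon: int = HORIZON, dt: float = 0.25):
        """Memoized scenario-independent population projection."""
        key = (horizon, dt)
        if key not in self._trajectories:
            self._trajectories[key] = dg.project_population(
                self.demographic_inputs, self.base_population, horizon, dt)
        return self._trajectories[key]

    def to_directory(self, path: str | Path) -> None:
        """Write the input bundle as delimited text files."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.base_population.to_frame().to_csv(path / "population.csv", index=False)
        self.prevalence_table.to_frame().to_csv(path / "prevalence.csv", index=False)
        self.demographic_inputs.birth_rate.to_frame(list(ETHNICITIES)).to_csv(
            path / "birth_rates.csv")
        self.demographic_inputs.death_rate.to_frame(list(range(N_AGES))).to_csv(
            path / "death_rates.csv")
        pd.Series(self.care_params.case_mix, name="fraction").rename_axis(
            "condition").to_csv(path / "case_mix.csv")
        self.workload_series.rename_axis("year").to_csv(path / "workload.csv")
        self.observed_history.rename_axis("year").to_csv(path / "observed_visits.csv")
        pd.Series(self.true_uptake, name="uptake").rename_axis("education").to_csv(
            path / "true_uptake.csv")


def replace_uptake(world: SyntheticWorld, uptake: np.ndarray) -> SyntheticWorld:
    """A shallow variant of a world with the uptake vector swapped in.

    Used when re-running scenarios per posterior draw; all other inputs
    (and the memoized population trajectory) are shared.
    """
    params = replace(
        world.care_params,
        uptake={e: float(uptake[i]) for i, e in enumerate(EDUCATIONS)},
    )
    patched = replace(world, care_params=params)
    patched._trajectories = world._trajectories
    return patched


def _age_pyramid(rng: np.random.Generator, centre: float, width: float,
                 floor: float = 0.0) -> np.ndarray:
    ages = np.arange(N_AGES, dtype=float)
    weights = np.exp(-0.5 * ((ages - centre) / width) ** 2) + floor
    weights *= np.exp(rng.normal(0.0, 0.03, N_AGES))   # seed-specific texture
    weights[95:] *= np.linspace(0.6, 0.05, N_AGES - 95)  # thin the extreme tail
    return weights / weights.sum()


def _education_by_age() -> np.ndarray:
    """(age, education) base-year attainment mix; under-25s not yet assigned."""
    mix = np.zeros((N_AGES, N_EDUCATIONS))
    mix[:25, 0] = 1.0
    ages = np.arange(25, N_AGES, dtype=float)
    frac = np.clip((ages - 25.0) / 60.0, 0.0, 1.0)[:, None]
    mix[25:] = (1.0 - frac) * _YOUNG_EDU + frac * _OLD_EDU
    return mix / mix.sum(axis=1, keepdims=True)


def _education_assignment(year: float) -> np.ndarray:
    """Labour-entry education mix drifting linearly toward tertiary by 2040."""
    frac = np.clip((year - BASE_YEAR) / (HORIZON - BASE_YEAR), 0.0, 1.0)
    dist = (1.0 - frac) * _YOUNG_EDU + frac * _EDU_2040
    return dist / dist.sum()


def _base_population(rng: np.random.Generator, scale: float,
                     pyramid: np.ndarray) -> dg.PopulationState:
    edu = _education_by_age()
    counts = (
        pyramid[:, None, None, None]
        * np.full((2,), 0.5)[None, :, None, None]
        * _ETHNIC_SHARES[None, None, :, None]
        * edu[:, None, None, :]
    )
    counts *= scale / counts.sum()
    return dg.PopulationState(BASE_YEAR, counts)


def _vital_rates(rng: np.random.Generator) -> tuple[TimeTable, TimeTable]:
    birth_years = np.arange(2000, 2014, dtype=float)
    base_rates = np.array([0.028, 0.042, 0.032, 0.030])  # births/repro-age female
    decline = np.linspace(1.0, 0.85, birth_years.size)
    births = base_rates[:, None] * decline[None, :]
    births *= np.exp(rng.normal(0.0, 0.02, births.shape))
    birth_table = TimeTable(birth_years, np.clip(births, 0.0, 1.0))

    death_years = np.arange(2003, 2014, dtype=float)
    ages = np.arange(N_AGES, dtype=float)
    gompertz = 3.0e-5 * np.exp(0.095 * ages)
    gompertz[0] += 0.002                              # infant mortality bump
    improvement = np.linspace(1.0, 0.97, death_years.size)
    deaths = np.clip(gompertz[:, None] * improvement[None, :], 2e-4, 0.5)
    death_table = TimeTable(death_years, deaths)
    return birth_table, death_table


def _migrant_profile() -> np.ndarray:
    ages = np.arange(N_AGES, dtype=float)
    age_w = np.clip(1.0 - np.abs(ages - 32.0) / 13.0, 0.0, None)  # 20..45 triangle
    profile = np.zeros(POP_SHAPE)
    eth = np.array([0.60, 0.10, 0.20, 0.10])
    edu_adult = np.array([0.02, 0.08, 0.35, 0.55])
    for a in range(N_AGES):
        if age_w[a] == 0:
            continue
        edu = edu_adult if a >= 25 else np.array([1.0, 0.0, 0.0, 0.0])
        profile[a] = age_w[a] * 0.5 * eth[:, None] * edu[None, :]
    return profile / profile.sum()


def _prevalence_table(rng: np.random.Generator,
                      dr_trend: YearPath | None = None) -> pv.PrevalenceTable:
    ages = np.arange(ADULT_MIN_AGE, N_AGES, dtype=float)
    p = np.zeros(pv.PREV_SHAPE)
    for c in CONDITIONS:
        plateau, inflection, slope = _PREVALENCE_SHAPES[c]
        plateau = plateau * float(np.exp(rng.normal(0.0, 0.05)))
        curve = plateau / (1.0 + np.exp(-(ages - inflection) / slope))
        eth = _ETHNICITY_MULT.get(c, _ETHNICITY_MULT["default"])
        edu = _EDUCATION_MULT.get(c, _EDUCATION_MULT["default"])
        p[CONDITION_INDEX[c]] = (
            curve[:, None, None] * eth[None, :, None] * edu[None, None, :])
    np.clip(p, 0.0, 0.97, out=p)
    if dr_trend is None:
        dr_trend = YearPath.ramp(BASE_YEAR, 1.0, HORIZON, 1.3)
    return pv.PrevalenceTable(p, dr_trend, base_year=BASE_YEAR)


def _calibrate_target_path(
    demo: dg.DemographicInputs,
    base_pop: dg.PopulationState,
    scale: float,
    target: float,
    tol: float = 1e-3,
) -> dg.DemographicInputs:
    """Calibrate the desired-population path so the projection attains it.

    The gap-closure migration rule chases the desired path with a lag, and
    natural decrease leaves a standing offset; as in the emulated setting —
    where the demographic module was calibrated against national statistics —
    the path level (reached at 2035, then flat) is adjusted by fixed-point
    iteration until the simulated total hits the stated horizon target.
    """
    level = target
    for _ in range(4):
        demo = replace(
            demo,
            desired_total_population=YearPath(
                np.array([BASE_YEAR, 2035.0]), np.array([scale, level])),
        )
        attained = dg.project_population(demo, base_pop, HORIZON)[-1].total()
        if abs(attained - target) < tol * target:
            break
        level += target - attained
    return demo


def _workload_series(rng: np.random.Generator) -> pd.Series:
    years = np.arange(2003, 2015)
    ratio = 6200.0 - 90.0 * (years - 2003) + rng.normal(0.0, 50.0, years.size)
    return pd.Series(np.clip(ratio, 1000.0, None), index=years, name="visits_per_oph")


def generate_world(
    seed: int,
    scale: float = 500_000.0,
    noise_sd: float = 0.03,
    history_end: int = 2020,
) -> SyntheticWorld:
    """Generate a full input bundle from a seed.

    The observed visit history (base year through ``history_end``,
    stratified by education) is produced by running the model itself at
    the true uptake factors and multiplying log-normal noise of standard
    deviation ``noise_sd`` — the recovery target for calibration.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if scale < 10_000:
        import warnings
        warnings.warn("scale below 10 000 gives unstable small cohorts")
    rng = np.random.default_rng(seed)
    pyramid = _age_pyramid(rng, centre=40.0, width=22.0, floor=0.05)
    base_pop = _base_population(rng, scale, pyramid)
    birth_table, death_table = _vital_rates(rng)

    target = scale * NATIONAL_TARGET / REAL_RESIDENT_POPULATION
    demo = dg.DemographicInputs(
        birth_rate=birth_table,
        death_rate=death_table,
        desired_total_population=YearPath(
            np.array([BASE_YEAR, 2035.0]), np.array([scale, target])),
        migrant_age_profile=_migrant_profile(),
        education_assignment=_education_assignment,
    )
    demo = _calibrate_target_path(demo, base_pop, scale, target)

    table = _prevalence_table(rng)
    care_params = cd.CareParameters()
    true_uptake = dict(cd.DEFAULT_UPTAKE)

    workload_series = _workload_series(rng)
    workload_model = wf.fit_workload(workload_series.index, workload_series.values)

    prevalent0 = cd.collapse_ethnicity(pv.prevalent_all(base_pop, table, BASE_YEAR))
    base_demand = (BASE_IN_CARE_FRACTION * float(prevalent0.sum())
                   * care_params.visit_rates()[0])

    sf = scale / REAL_RESIDENT_POPULATION
    rates = wf.PipelineRates(
        admissions=YearPath.constant(300.0 * sf),
        residency_intake=YearPath.constant(9.0 * sf),
        desired_medical_officers=YearPath.constant(25.0 * sf * 10),
    )

    world = SyntheticWorld(
        seed=seed,
        scale=scale,
        base_year=BASE_YEAR,
        base_population=base_pop,
        demographic_inputs=demo,
        prevalence_table=table,
        care_params=care_params,
        pipeline_rates=rates,
        workload_series=workload_series,
        workload_model=workload_model,
        true_uptake=true_uptake,
        base_demand_visits=base_demand,
        observed_history=pd.DataFrame(),
        noise_sd=noise_sd,
    )
    world.observed_history = _observed_history(world, rng, history_end, noise_sd)
    return world


def _observed_history(
    world: SyntheticWorld, rng: np.random.Generator, history_end: int, noise_sd: float
) -> pd.DataFrame:
    years = list(range(world.base_year, history_end + 1))
    sim = UptakeDemandSimulator(
        world, years, population_trajectory=world.population_trajectory(history_end))
    truth = np.array([world.true_uptake[e] for e in EDUCATIONS])
    series = sim.series(truth)[list(EDUCATIONS)]
    if noise_sd > 0:
        noise = np.exp(rng.normal(0.0, noise_sd, series.shape))
        series = series * noise
    series["total"] = series[list(EDUCATIONS)].sum(axis=1)
    return series


def generate_aging_stress_world(seed: int, scale: float = 500_000.0) -> SyntheticWorld:
    """A mechanism-probe world with a strong old-age bulge.

    Designed to isolate the age-prevalence mechanism: mortality is
    age-flat, uptake is education-uniform and fast (0.9/year), there is
    no migration and no decanting, so with a flat prevalence table demand
    growth collapses onto 40+ head-count growth, while age-increasing
    prevalence makes demand outgrow the head count.
    """
    rng = np.random.default_rng(seed)
    # Bulge kept entirely above age 40 over a flat floor: the cohorts
    # crossing 40 are then near-constant, so the 40+ head count evolves at a
    # steady rate and the care stocks' short tracking lag cancels out of the
    # growth comparison.
    pyramid = _age_pyramid(rng, centre=62.0, width=9.0, floor=0.15)
    base_pop = _base_population(rng, scale, pyramid)

    birth_years = np.arange(2000, 2014, dtype=float)
    births = np.tile(np.array([0.03, 0.03, 0.03, 0.03])[:, None], (1, birth_years.size))
    birth_table = TimeTable(birth_years, births)
    death_table = TimeTable.constant(
        np.arange(2003, 2014, dtype=float), np.full(N_AGES, 0.01))

    demo = dg.DemographicInputs(
        birth_rate=birth_table,
        death_rate=death_table,
        desired_total_population=YearPath.constant(scale),
        migrant_age_profile=_migrant_profile(),
        fraction_immigrating=0.0,
        education_assignment=None,
    )

    table = _prevalence_table(rng, dr_trend=YearPath.constant(1.0))
    # Treatment completion is disabled (effectively lifelong care for every
    # condition): the completed-care stock has a 1/mortality-scale memory that
    # cannot track a shifting age structure and would confound the
    # flat-prevalence control.  In-care stocks then follow the prevalent pool
    # with a ~1/(uptake+mortality) lag of about two years.
    care_params = cd.CareParameters(
        uptake={e: 0.9 for e in EDUCATIONS},
        duration_in_care={c: 1e9 for c in cd.CURABLE_DURATIONS})
    workload_series = _workload_series(rng)

    prevalent0 = cd.collapse_ethnicity(pv.prevalent_all(base_pop, table, BASE_YEAR))
    base_demand = (BASE_IN_CARE_FRACTION * float(prevalent0.sum())
                   * care_params.visit_rates()[0])

    return SyntheticWorld(
        seed=seed,
        scale=scale,
        base_year=BASE_YEAR,
        base_population=base_pop,
        demographic_inputs=demo,
        prevalence_table=table,
        care_params=care_params,
        pipeline_rates=wf.PipelineRates(),
        workload_series=workload_series,
        workload_model=wf.fit_workload(workload_series.index, workload_series.values),
        true_uptake={e: 0.9 for e in EDUCATIONS},
        base_demand_visits=base_demand,
        observed_history=pd.DataFrame(),
        noise_sd=0.0,
    )


def flatten_prevalence(
    table: pv.PrevalenceTable, pop: dg.PopulationState, year: float
) -> pv.PrevalenceTable:
    """Replace each condition's rates by one cell-uniform proportion.

    The uniform proportion preserves the condition's prevalent total in
    the given population, so prevalent cases become exactly proportional
    to the 40+ head count thereafter — the degenerate control for the
    aging-mechanism comparison.
    """
    counts = pv.prevalent_all(pop, table, year)
    adults = float(pop.counts[ADULT_MIN_AGE:].sum())
    flat = counts.sum(axis=(1, 2, 3)) / adults
    p = np.broadcast_to(
        flat[:, None, None, None], pv.PREV_SHAPE).copy()
    return pv.PrevalenceTable(np.clip(p, 0.0, 1.0), YearPath.constant(1.0),
                              base_year=table.base_year)


def demand_vs_population_growth(
    world: SyntheticWorld,
    flat_prevalence: bool,
    start: int = 2015,
    end: int = 2040,
    dt: float = 0.25,
) -> tuple[float, float]:
    """Growth of visit demand vs growth of the 40+ head count, start->end.

    Care stocks start at their analytic equilibrium in the world's base
    year and spin up to ``start`` before measuring, so initialization
    transients do not contaminate the growth comparison.  Returns
    ``(demand_growth, population_growth)`` as fractions.
    """
    traj = world.population_trajectory(end, dt)
    pop_by_year = {int(round(s.year)): s for s in traj}
    table = world.prevalence_table
    if flat_prevalence:
        table = flatten_prevalence(table, pop_by_year[start], start)
    prev = {
        y: cd.collapse_ethnicity(pv.prevalent_all(pop_by_year[y], table, y))
        for y in range(world.base_year, end + 1)
    }
    params = world.care_params
    mu0 = world.demographic_inputs.death_rate.at(world.base_year)[ADULT_MIN_AGE:]
    care = cd.equilibrium_care_state(prev[world.base_year], params, mu0,
                                     world.base_year)
    n_sub = round(1.0 / dt)
    demand_at = {}
    for year in range(world.base_year, end):
        mu = world.demographic_inputs.death_rate.at(year)[ADULT_MIN_AGE:]
        for _ in range(n_sub):
            untreated = cd.untreated_pool(prev[year], care)
            flow = cd.new_patient_flow(untreated, params, year)
            completion = cd.completion_flow(care, params)
            care = cd.step_care(care, flow, completion, mu, dt)
        demand_at[year + 1], _ = cd.demand_visits(care, params)
    demand_growth = demand_at[end] / demand_at[start] - 1.0
    pop40 = {y: float(pop_by_year[y].counts[ADULT_MIN_AGE:].sum()) for y in (start, end)}
    pop_growth = pop40[end] / pop40[start] - 1.0
    return demand_growth, pop_growth
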