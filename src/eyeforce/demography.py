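"""Cohort-component projection of the resident population.

The resident population is carried on a grid of 1-year age cohorts
(0..99 plus an absorbing 100+ bin) by gender, ethnicity and educational
attainment.  Four flows change it: births, deaths, and net migration
steering the total toward a desired national population path, plus the
deterministic aging shift at whole-year boundaries.

Integration is explicit Euler at a sub-annual step (default 0.25 year);
cohort shifting — and the one-off assignment of educational attainment to
the cohort entering the labour force — happens only when the clock crosses
a whole-year boundary, which keeps 1-year cohorts well defined while the
flows remain continuous-time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dimensions import (
    EDUCATIONS,
    EDUCATION_INDEX,
    ETHNICITIES,
    GENDERS,
    N_AGES,
    N_EDUCATIONS,
    OPEN_AGE,
    POP_SHAPE,
    is_whole_year,
)
from .timeseries import TimeTable, YearPath

REPRODUCTIVE_AGES = slice(15, 50)  # ages 15..49 inclusive

__all__ = [
    "PopulationState",
    "DemographicInputs",
    "StepAudit",
    "birth_flow",
    "migration_flow",
    "step_population",
    "project_population",
]


@dataclass
class PopulationState:
    """Resident head counts on the age x gender x ethnicity x education grid."""

    year: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != POP_SHAPE:
            raise ValueError(f"counts must have shape {POP_SHAPE}, got {counts.shape}")
        if not np.all(np.isfinite(counts)):
            raise ValueError("counts must be finite")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        self.counts = counts

    def total(self) -> float:
        return float(self.counts.sum())

    def copy(self) -> "PopulationState":
        return PopulationState(self.year, self.counts.copy())

    def by_age(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2, 3))

    def mean_age(self) -> float:
        by_age = self.by_age()
        return float(np.average(np.arange(N_AGES), weights=by_age))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (year, age, gender, ethnicity, education, count)."""
        idx = pd.MultiIndex.from_product(
            [range(N_AGES), GENDERS, ETHNICITIES, EDUCATIONS],
            names=["age", "gender", "ethnicity", "education"],
        )
        frame = pd.DataFrame({"count": self.counts.ravel()}, index=idx).reset_index()
        frame.insert(0, "year", int(round(self.year)))
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PopulationState":
        counts = np.zeros(POP_SHAPE)
        for row in frame.itertuples(index=False):
            counts[
                int(row.age),
                GENDERS.index(row.gender),
                ETHNICITIES.index(row.ethnicity),
                EDUCATION_INDEX[row.education],
            ] = row.count
        return cls(float(frame["year"].iloc[0]), counts)


@dataclass
class DemographicInputs:
    """Vital rates, migration steering and education assignment.

    ``birth_rate`` is births per reproductive-age (15-49) female per year, by
    ethnicity; ``death_rate`` is deaths per person per year by age.  Net
    migration closes a fraction (default 0.3/year) of the gap between the
    current resident total and the desired national population path; the
    ``resident_fraction`` converts the national target (which may include
    non-residents) into resident terms.
    """

    birth_rate: TimeTable                      # rows = ethnicities
    death_rate: TimeTable                      # rows = ages
    desired_total_population: YearPath
    migrant_age_profile: np.ndarray            # POP_SHAPE, sums to 1
    birth_rate_multiplier: float = 1.0
    fraction_female: float = 0.5
    fraction_immigrating: float = 0.3
    resident_fraction: float = 1.0
    education_assignment: Callable[[float], np.ndarray] | None = None
    education_entry_age: int = 25

    def __post_init__(self) -> None:
        profile = np.asarray(self.migrant_age_profile, dtype=float)
        if profile.shape != POP_SHAPE:
            raise ValueError("migrant_age_profile must match the population grid")
        if abs(profile.sum() - 1.0) > 1e-9:
            raise ValueError("migrant_age_profile must sum to 1")
        if np.any(profile < 0):
            raise ValueError("migrant_age_profile must be non-negative")
        if not (0.0 <= self.fraction_female <= 1.0):
            raise ValueError("fraction_female must lie in [0, 1]")
        if not (0.0 <= self.fraction_immigrating <= 1.0):
            raise ValueError("fraction_immigrating must lie in [0, 1]")
        if np.any(self.birth_rate.values < 0) or np.any(self.birth_rate.values > 1):
            raise ValueError("birth rates must lie in [0, 1]")
        if np.any(self.death_rate.values < 0) or np.any(self.death_rate.values > 1):
            raise ValueError("death rates must lie in [0, 1]")
        self.migrant_age_profile = profile

    @property
    def fraction_male(self) -> float:
        return 1.0 - self.fraction_female


@dataclass
class StepAudit:
    """Flow totals for one Euler step, for conservation checks."""

    births: float
    deaths: float
    net_migration: float
    dt: float
    old_total: float
    new_total: float

    @property
    def imbalance(self) -> float:
        """Relative conservation error of the step (should be ~machine eps)."""
        expected = (self.births + self.net_migration - self.deaths) * self.dt
        scale = max(abs(self.old_total), 1.0)
        return abs((self.new_total - self.old_total) - expected) / scale


def birth_flow(
    state: PopulationState, inputs: DemographicInputs, year: float
) -> np.ndarray:
    """Births per year by gender x ethnicity.

    Newborns per ethnicity are the ethnicity's birth rate times the
    multiplier times its reproductive-age (15-49) female population, split
    by ``fraction_female``.  The inflow enters age 0 in the "none"
    education stratum (see :func:`step_population`).
    """
    rates = inputs.birth_rate.at(year)
    if np.any(rates < 0):
        raise ValueError("birth rates must be non-negative")
    females = state.counts[REPRODUCTIVE_AGES, 0, :, :].sum(axis=(0, 2))
    newborns = rates * inputs.birth_rate_multiplier * females
    return np.stack(
        [newborns * inputs.fraction_female, newborns * inputs.fraction_male]
    )


def migration_flow(
    state: PopulationState, inputs: DemographicInputs, year: float
) -> np.ndarray:
    """Net migration per year on the full grid (negative = emigration).

    The annual net flow closes ``fraction_immigrating`` of the gap between
    the resident-equivalent desired total and the current resident total.
    Immigration is allocated over cells by the migrant age profile;
    emigration is spread proportionally to current counts.
    """
    target = inputs.desired_total_population(year) * inputs.resident_fraction
    gap = target - state.total()
    net = inputs.fraction_immigrating * gap
    if net >= 0:
        return net * inputs.migrant_age_profile
    total = state.total()
    if total <= 0:
        return np.zeros(POP_SHAPE)
    return net * state.counts / total


def _shift_cohorts(counts: np.ndarray, inputs: DemographicInputs, year: float) -> np.ndarray:
    """Annual aging shift with 100+ pooling and labour-force education entry."""
    shifted = np.empty_like(counts)
    shifted[OPEN_AGE] = counts[OPEN_AGE] + counts[OPEN_AGE - 1]
    shifted[1:OPEN_AGE] = counts[: OPEN_AGE - 1]
    shifted[0] = 0.0
    if inputs.education_assignment is not None:
        entry = inputs.education_entry_age
        dist = np.asarray(inputs.education_assignment(year), dtype=float)
        if dist.shape != (N_EDUCATIONS,) or abs(dist.sum() - 1.0) > 1e-9:
            raise ValueError("education assignment must be a distribution over strata")
        cohort_total = shifted[entry].sum(axis=-1, keepdims=True)
        shifted[entry] = cohort_total * dist
    return shifted


def step_population(
    state: PopulationState,
    inputs: DemographicInputs,
    dt: float,
    return_audit: bool = False,
) -> PopulationState | tuple[PopulationState, StepAudit]:
    """Advance the population by one Euler step of length ``dt`` years.

    Deaths, births and net migration are applied as flows times ``dt``;
    if the step lands on a whole-year boundary every cohort then ages by
    one year (survivors of 99 and of 100+ pool in 100+).
    """
    if dt <= 0 or dt > 1:
        raise ValueError("dt must lie in (0, 1]")
    year = state.year
    counts = state.counts
    death_rates = inputs.death_rate.at(year)
    deaths = death_rates[:, None, None, None] * counts * dt
    births = birth_flow(state, inputs, year)
    migration = migration_flow(state, inputs, year)

    new_counts = counts - deaths + migration * dt
    new_counts[0, :, :, EDUCATION_INDEX["none"]] += births * dt
    # Emigration at an extreme rate could overshoot a cell; clamp guards it.
    np.clip(new_counts, 0.0, None, out=new_counts)

    new_year = year + dt
    if is_whole_year(new_year):
        new_year = round(new_year)
        new_counts = _shift_cohorts(new_counts, inputs, new_year)
    new_state = PopulationState(new_year, new_counts)
    if not return_audit:
        return new_state
    audit = StepAudit(
        births=float(births.sum()),
        deaths=float(deaths.sum()) / dt,
        net_migration=float(migration.sum()),
        dt=dt,
        old_total=state.total(),
        new_total=new_state.total(),
    )
    return new_state, audit


def project_population(
    inputs: DemographicInputs,
    base_state: PopulationState,
    horizon_year: int,
    dt: float = 0.25,
    collect_audits: list[StepAudit] | None = None,
) -> list[PopulationState]:
    """Project from the base year to the horizon; one state per whole year.

    The trajectory is the composition of :func:`step_population` steps and is
    deterministic given the inputs.
    """
    if horizon_year < base_state.year:
        raise ValueError("horizon_year must not precede the base year")
    n_sub = round(1.0 / dt)
    if abs(n_sub * dt - 1.0) > 1e-9:
        raise ValueError("1/dt must be an integer")
    trajectory = [base_state.copy()]
    state = base_state.copy()
    n_years = int(round(horizon_year - base_state.year))
    for _ in range(n_years):
        for _ in range(n_sub):
            if collect_audits is not None:
                state, audit = step_population(state, inputs, dt, return_audit=True)
                collect_audits.append(audit)
            else:
                state = step_population(state, inputs, dt)
        trajectory.append(state.copy())
    return trajectory


def trajectory_to_frame(trajectory: Sequence[PopulationState]) -> pd.DataFrame:
    """Concatenate annual states into one long-format table."""
    return pd.concat([s.to_frame() for s in trajectory], ignore_index=True)
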