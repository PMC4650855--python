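"""Prevalent cases of nine eye conditions in the 40+ resident population.

Per-condition prevalence proportions, stratified by single-year age (40
to 100+), ethnicity and educational attainment, are applied to the
projected population.  Conditions are modelled marginally — a person may
be counted under several conditions — and under-40 prevalence is set to
zero (under-40 service use is absorbed by the uptake factors downstream).

Diabetic retinopathy additionally carries a calendar-year multiplier that
encodes the anticipated rise in diabetes over the projection horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import PopulationState
from .dimensions import (
    ADULT_MIN_AGE,
    CONDITIONS,
    CONDITION_INDEX,
    EDUCATIONS,
    ETHNICITIES,
    N_ADULT_AGES,
    N_CONDITIONS,
    N_EDUCATIONS,
    N_ETHNICITIES,
)
from .timeseries import YearPath

__all__ = [
    "PrevalenceTable",
    "prevalent_counts",
    "prevalent_all",
    "prevalence_projection_table",
]

#: Prevalence grid shape (condition, adult age, ethnicity, education).
PREV_SHAPE = (N_CONDITIONS, N_ADULT_AGES, N_ETHNICITIES, N_EDUCATIONS)


@dataclass
class PrevalenceTable:
    """Per-condition prevalence proportions on the adult grid.

    ``p[c, a, e, d]`` is the proportion of the population aged
    ``40 + a`` of ethnicity ``e`` and education ``d`` who have condition
    ``c``.  ``dr_trend`` is a dimensionless multiplier trajectory applied
    to diabetic retinopathy only, equal to 1 in the base year.
    """

    p: np.ndarray
    dr_trend: YearPath
    base_year: float = 2010.0

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != PREV_SHAPE:
            raise ValueError(f"p must have shape {PREV_SHAPE}, got {p.shape}")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("prevalence proportions must lie in [0, 1]")
        if abs(self.dr_trend(self.base_year) - 1.0) > 1e-9:
            raise ValueError("dr_trend must equal 1 in the base year")
        self.p = p

    def multiplier(self, condition: str, year: float) -> float:
        if condition == "dr":
            m = self.dr_trend(year)
            if m < 0:
                raise ValueError("dr_trend must be non-negative")
            return m
        return 1.0

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (condition, age, ethnicity, education, proportion)."""
        idx = pd.MultiIndex.from_product(
            [CONDITIONS, range(ADULT_MIN_AGE, ADULT_MIN_AGE + N_ADULT_AGES),
             ETHNICITIES, EDUCATIONS],
            names=["condition", "age", "ethnicity", "education"],
        )
        return pd.DataFrame({"proportion": self.p.ravel()}, index=idx).reset_index()


def _adult_population(pop: PopulationState) -> np.ndarray:
    """40+ counts with gender marginalized out: (adult age, ethnicity, education)."""
    return pop.counts[ADULT_MIN_AGE:].sum(axis=1)


def prevalent_counts(
    pop: PopulationState, table: PrevalenceTable, condition: str, year: float
) -> np.ndarray:
    """Prevalent cases of one condition by adult age x ethnicity x education.

    Ages below 40 contribute zero by construction.
    """
    c = CONDITION_INDEX[condition]
    adults = _adult_population(pop)
    return adults * table.p[c] * table.multiplier(condition, year)


def prevalent_all(pop: PopulationState, table: PrevalenceTable, year: float) -> np.ndarray:
    """Prevalent cases for all conditions: (condition, adult age, ethnicity, education)."""
    adults = _adult_population(pop)
    counts = table.p * adults[None, :, :, :]
    counts[CONDITION_INDEX["dr"]] *= table.multiplier("dr", year)
    return counts


def prevalence_projection_table(
    pop_trajectory: list[PopulationState],
    table: PrevalenceTable,
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Total prevalent cases by condition x output year.

    Defaults to 5-year intervals over the trajectory.  Values are exact
    cell sums; display rounding (nearest 100) is applied by the report
    layer, never here.
    """
    by_year = {int(round(s.year)): s for s in pop_trajectory}
    if years is None:
        span = sorted(by_year)
        years = [y for y in span if (y - span[0]) % 5 == 0]
    missing = [y for y in years if y not in by_year]
    if missing:
        raise ValueError(f"trajectory does not cover years {missing}")
    out = pd.DataFrame(index=pd.Index(CONDITIONS, name="condition"),
                       columns=years, dtype=float)
    for y in years:
        totals = prevalent_all(by_year[y], table, y).sum(axis=(1, 2, 3))
        out[y] = totals
    return out
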