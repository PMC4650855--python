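"""Small containers for calendar-year rate series.

Administrative rate tables cover a finite span of years (e.g. death rates
2003-2013).  Outside that span the convention throughout the package is
carry-forward/backward of the nearest value; policy paths use linear
interpolation instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TimeTable:
    """A rate table over entities x calendar years with nearest-year lookup.

    ``values[i, j]`` is the rate for entity ``i`` (an age, an ethnicity, ...)
    in calendar year ``years[j]``.  Lookups clamp to the covered span, which
    implements the hold-last-value convention for projections beyond the data.
    """

    years: np.ndarray
    values: np.ndarray  # (n_entities, n_years)

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != years.size:
            raise ValueError("values must be (n_entities, n_years)")
        if np.any(np.diff(years) <= 0):
            raise ValueError("years must be strictly increasing")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)

    def at(self, year: float) -> np.ndarray:
        """Column of rates for ``year``, clamped to the covered span."""
        j = int(np.searchsorted(self.years, year, side="right")) - 1
        j = min(max(j, 0), self.years.size - 1)
        return self.values[:, j]

    def to_frame(self, index: list[str] | np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=index, columns=self.years.astype(int))

    @classmethod
    def constant(cls, years: np.ndarray, column: np.ndarray) -> "TimeTable":
        """A table holding the same column for every listed year."""
        years = np.asarray(years, dtype=float)
        column = np.asarray(column, dtype=float)
        return cls(years, np.tile(column[:, None], (1, years.size)))


@dataclass(frozen=True)
class YearPath:
    """A scalar trajectory over calendar years, linear between knots.

    Values are clamped to the end knots outside the covered span, so a path
    ending at its target stays at that target thereafter.
    """

    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if years.shape != values.shape or years.ndim != 1:
            raise ValueError("years and values must be matching 1-d arrays")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)

    def __call__(self, year: float) -> float:
        return float(np.interp(year, self.years, self.values))

    @classmethod
    def constant(cls, value: float) -> "YearPath":
        return cls(np.array([0.0, 1.0]), np.array([value, value]))

    @classmethod
    def ramp(cls, y0: float, v0: float, y1: float, v1: float) -> "YearPath":
        """Linear ramp from ``v0`` at ``y0`` to ``v1`` at ``y1``, flat outside."""
        return cls(np.array([y0, y1]), np.array([v0, v1]))
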