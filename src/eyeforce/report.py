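"""Projection tables, percent-change and ratio summaries.

Reporting follows the conventions of published workforce projections:
case counts and visit volumes are displayed rounded to the nearest 100,
head counts as integers, percent changes as half-up-rounded integer
percents, and scenario ratios to two decimals.  Display rounding never
feeds back into computation — all arithmetic runs on unrounded values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "percent_change",
    "scenario_ratio",
    "round_display",
    "format_cell",
    "ProjectionTable",
    "make_table",
]


def _half_up(value: float, decimals: int = 0) -> float:
    exp = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(exp, rounding=ROUND_HALF_UP))


def percent_change(v0: float, v1: float) -> int:
    """Integer percent change from ``v0`` to ``v1``, rounded half up."""
    if v0 <= 0:
        raise ValueError("baseline value must be positive")
    return int(_half_up(100.0 * (v1 - v0) / v0))


def scenario_ratio(a: float, b: float) -> float:
    """Ratio ``a/b`` rounded half up to two decimals."""
    if b <= 0:
        raise ValueError("denominator must be positive")
    return _half_up(a / b, 2)


def round_display(value: float, round_to: int = 100) -> int:
    """Display rounding to the nearest multiple of ``round_to`` (half up)."""
    if round_to <= 0:
        raise ValueError("round_to must be positive")
    return int(_half_up(value / round_to) * round_to)


def format_cell(central: float, lo: float | None = None, hi: float | None = None,
                round_to: int = 100) -> str:
    """Format a table cell, e.g. ``718 500 [537 500-927 500]``."""

    def fmt(v: float) -> str:
        return f"{round_display(v, round_to):,}".replace(",", " ")

    if lo is None or hi is None:
        return fmt(central)
    return f"{fmt(central)} [{fmt(lo)}–{fmt(hi)}]"


@dataclass
class ProjectionTable:
    """Outcome x scenario rows over projection years, with optional intervals.

    ``central`` is indexed by (outcome, scenario) with year columns;
    ``lo``/``hi`` mirror it where credible intervals are available.
    The percent-change column compares the 2015 and 2040 central values
    and is computed from unrounded numbers.
    """

    central: pd.DataFrame
    lo: pd.DataFrame | None = None
    hi: pd.DataFrame | None = None
    round_to: Mapping[str, int] = field(default_factory=dict)
    change_years: tuple[int, int] = (2015, 2040)

    def __post_init__(self) -> None:
        if self.lo is not None:
            bad = (self.lo.values > self.central.values + 1e-9) | (
                self.central.values > self.hi.values + 1e-9)
            if bad.any():
                raise ValueError("interval bounds must bracket the central values")

    def pct_change(self) -> pd.Series:
        y0, y1 = self.change_years
        return pd.Series(
            {idx: percent_change(self.central.loc[idx, y0], self.central.loc[idx, y1])
             for idx in self.central.index})

    def to_text(self) -> str:
        """Bracketed display layout, one row per outcome/scenario."""
        y0, y1 = self.change_years
        lines = []
        header = ["outcome/scenario"] + [str(y) for y in self.central.columns]
        header.append(f"% change {y0}-{y1}")
        lines.append("\t".join(header))
        for idx in self.central.index:
            rt = self.round_to.get(idx[0] if isinstance(idx, tuple) else idx, 100)
            cells = []
            for y in self.central.columns:
                lo = self.lo.loc[idx, y] if self.lo is not None else None
                hi = self.hi.loc[idx, y] if self.hi is not None else None
                cells.append(format_cell(self.central.loc[idx, y], lo, hi, rt))
            label = " / ".join(idx) if isinstance(idx, tuple) else str(idx)
            lines.append("\t".join([label] + cells + [str(self.pct_change()[idx])]))
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        """Machine-readable output preserving unrounded central values."""
        frame = self.central.copy()
        frame.columns = [f"central_{y}" for y in frame.columns]
        if self.lo is not None:
            for y in self.lo.columns:
                frame[f"lo_{y}"] = self.lo[y]
                frame[f"hi_{y}"] = self.hi[y]
        frame.to_csv(path)

    @classmethod
    def from_csv(cls, path, n_index_cols: int = 2) -> "ProjectionTable":
        frame = pd.read_csv(path, index_col=list(range(n_index_cols)),
                            float_precision="round_trip")
        central = frame[[c for c in frame.columns if c.startswith("central_")]].copy()
        central.columns = [int(c.split("_")[1]) for c in central.columns]
        lo_cols = [c for c in frame.columns if c.startswith("lo_")]
        lo = hi = None
        if lo_cols:
            lo = frame[lo_cols].copy()
            lo.columns = [int(c.split("_")[1]) for c in lo_cols]
            hi = frame[[c.replace("lo_", "hi_") for c in lo_cols]].copy()
            hi.columns = lo.columns
        return cls(central, lo, hi)


def make_table(
    trajectories: Mapping[tuple[str, str], pd.Series],
    intervals: Mapping[tuple[str, str], pd.DataFrame] | None = None,
    years: Sequence[int] = (2010, 2015, 2020, 2025, 2030, 2035, 2040),
    round_to: Mapping[str, int] | None = None,
    change_years: tuple[int, int] | None = None,
) -> ProjectionTable:
    """Assemble a projection table from annual output series.

    ``trajectories`` maps (outcome, scenario) to an annual series;
    ``intervals`` optionally maps the same keys to lo/hi frames from
    :func:`~eyeforce.calibration.propagate_uncertainty`.
    """
    years = list(years)
    index = pd.MultiIndex.from_tuples(trajectories.keys(),
                                      names=["outcome", "scenario"])
    central = pd.DataFrame(index=index, columns=years, dtype=float)
    lo = hi = None
    for key, series in trajectories.items():
        missing = [y for y in years if y not in series.index]
        if missing:
            raise ValueError(f"trajectory {key} missing years {missing}")
        central.loc[key, years] = series.loc[years].to_numpy(dtype=float)
    if intervals:
        lo = pd.DataFrame(index=index, columns=years, dtype=float)
        hi = pd.DataFrame(index=index, columns=years, dtype=float)
        for key in trajectories:
            band = intervals.get(key)
            if band is None:
                lo.loc[key, years] = central.loc[key, years]
                hi.loc[key, years] = central.loc[key, years]
            else:
                lo.loc[key, years] = band.loc[years, "lo"].to_numpy(dtype=float)
                hi.loc[key, years] = band.loc[years, "hi"].to_numpy(dtype=float)
        # Central runs can sit marginally outside thinned percentile bands.
        lo = pd.DataFrame(np.minimum(lo.values, central.values),
                          index=index, columns=years)
        hi = pd.DataFrame(np.maximum(hi.values, central.values),
                          index=index, columns=years)
    if change_years is None:
        change_years = (2015, 2040) if {2015, 2040} <= set(years) else (years[0], years[-1])
    return ProjectionTable(central, lo, hi, round_to=dict(round_to or {}),
                           change_years=change_years)
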