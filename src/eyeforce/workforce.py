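"""Ophthalmologist training pipeline, hiring, and workforce requirement.

The supply side is a training conveyor: medical students (5-year course)
graduate into house officers, some enter other residencies; house
officers feed the medical-officer pool (hired against an exogenous
desired headcount) and the ophthalmology residency, a 5-stage one-year
aging chain whose annual intake is the policy lever.  Residency
graduates are hired into the ophthalmologist stock up to the desired
hiring (gap plus expected attrition); the surplus leaves the public
system permanently.  Stage advancement, graduation and hiring happen at
whole-year boundaries; all other flows are continuous.

The demand side converts annual visit demand into required headcount by
dividing by the workload (patient-visits-per-ophthalmologist ratio),
fitted to a historical series and optionally moderated by a scenario
multiplier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .timeseries import YearPath

__all__ = [
    "WorkforceState",
    "PipelineRates",
    "WorkloadModel",
    "fit_workload",
    "required_ophthalmologists",
    "desired_hiring",
    "step_pipeline",
    "simulate_supply",
    "plan_required_intake",
    "InfeasibleIntakeError",
]

#: Average split of an ophthalmologist's work hours (administrative data);
#: carried as metadata — the workload ratio already reflects clinical time.
DEFAULT_WORK_HOURS_SPLIT = {
    "clinical": 0.86,
    "research": 0.09,
    "teaching": 0.02,
    "administration": 0.03,
}


class InfeasibleIntakeError(RuntimeError):
    """No intake within bounds can meet the required trajectory."""


@dataclass
class WorkforceState:
    """Stocks of the training pipeline at a point in time.

    ``residents`` holds the residency aging chain, one slot per training
    year; intake accumulates in the first slot and the chain advances at
    whole-year boundaries, so a resident entering in year t graduates at
    the start of year t + duration.
    """

    year: float
    medical_students: float
    house_officers: float
    medical_officers: float
    residents: np.ndarray
    ophthalmologists: float

    def __post_init__(self) -> None:
        self.residents = np.asarray(self.residents, dtype=float)
        stocks = [self.medical_students, self.house_officers, self.medical_officers,
                  self.ophthalmologists, *self.residents]
        if any(s < -1e-9 for s in stocks):
            raise ValueError("pipeline stocks must be non-negative")

    def total(self) -> float:
        return float(
            self.medical_students + self.house_officers + self.medical_officers
            + self.residents.sum() + self.ophthalmologists
        )

    def copy(self) -> "WorkforceState":
        return WorkforceState(
            self.year, self.medical_students, self.house_officers,
            self.medical_officers, self.residents.copy(),
            self.ophthalmologists,
        )


@dataclass
class PipelineRates:
    """Flow rates and policy levers of the training pipeline."""

    admissions: YearPath = field(default_factory=lambda: YearPath.constant(30.0))
    dropout_rate: float = 0.0
    med_school_duration: float = 5.0
    fraction_other_residency: float = 0.1
    ho_attrition: float = 0.1
    mo_attrition: YearPath = field(default_factory=lambda: YearPath.constant(0.1))
    oph_attrition: float = 0.03
    residency_duration: int = 5
    residency_intake: YearPath = field(default_factory=lambda: YearPath.constant(9.0))
    desired_medical_officers: YearPath = field(default_factory=lambda: YearPath.constant(20.0))
    fraction_grads_other_jobs: float = 0.0
    work_hours_split: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WORK_HOURS_SPLIT))

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "fraction_other_residency", "ho_attrition",
                     "oph_attrition", "fraction_grads_other_jobs"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(sum(self.work_hours_split.values()) - 1.0) > 1e-9:
            raise ValueError("work_hours_split must sum to 1")
        if self.residency_duration < 1:
            raise ValueError("residency_duration must be at least 1 year")


@dataclass
class WorkloadModel:
    """Visits-per-ophthalmologist ratio as a function of calendar year."""

    intercept: float
    slope: float
    last_data_year: float
    extrapolation: str = "constant"   # "constant" holds the last fitted value
    workload_multiplier: float | YearPath = 1.0

    def multiplier_at(self, year: float) -> float:
        m = self.workload_multiplier
        return float(m(year)) if callable(m) else float(m)

    def workload(self, year: float) -> float:
        """Fitted ratio, before the scenario multiplier."""
        y = year
        if self.extrapolation == "constant":
            y = min(year, self.last_data_year)
        w = self.intercept + self.slope * y
        if w <= 0:
            raise ValueError(f"fitted workload non-positive at year {year}")
        return w

    def effective_workload(self, year: float) -> float:
        return self.workload(year) * self.multiplier_at(year)


def fit_workload(
    years: Sequence[float],
    visits_per_oph: Sequence[float],
    extrapolation: str = "constant",
) -> WorkloadModel:
    """Least-squares linear fit of the historical workload series."""
    years = np.asarray(years, dtype=float)
    ratio = np.asarray(visits_per_oph, dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("workload series must be positive")
    slope, intercept = np.polyfit(years, ratio, 1)
    return WorkloadModel(float(intercept), float(slope), float(years.max()),
                         extrapolation=extrapolation)


def required_ophthalmologists(
    demand: float, model: WorkloadModel, year: float
) -> tuple[float, int]:
    """Headcount required to serve an annual visit demand.

    Returns ``(continuous, reported)`` where the reported value is the
    continuous requirement rounded up to an integer; all downstream
    arithmetic uses the continuous value.
    """
    if demand < 0:
        raise ValueError("demand must be non-negative")
    w = model.effective_workload(year)
    if w <= 0:
        raise ValueError("effective workload must be positive")
    req = demand / w
    return req, int(math.ceil(req - 1e-9))


def desired_hiring(required: float, current: float, attrition_rate: float) -> float:
    """Gap plus expected attrition, clamped at zero (no negative hiring)."""
    if required < 0 or current < 0 or attrition_rate < 0:
        raise ValueError("inputs must be non-negative")
    return max(0.0, (required - current) + attrition_rate * current)


@dataclass
class PipelineAudit:
    """Flow totals over one step, for pipeline conservation checks."""

    inflow: float        # people entering the system during the step
    outflow: float       # people leaving the system during the step
    old_total: float
    new_total: float

    @property
    def imbalance(self) -> float:
        scale = max(abs(self.old_total), 1.0)
        return abs((self.new_total - self.old_total) - (self.inflow - self.outflow)) / scale


def step_pipeline(
    state: WorkforceState,
    rates: PipelineRates,
    hires_demanded: float,
    dt: float,
    return_audit: bool = False,
) -> WorkforceState | tuple[WorkforceState, PipelineAudit]:
    """Advance the pipeline by one Euler step of length ``dt`` years.

    ``hires_demanded`` (people/year) caps how many residency graduates are
    hired at the next whole-year boundary; the surplus exits the public
    system.  Intake is bounded by the residency-intake policy series and
    by the upstream house-officer/medical-officer pools.
    """
    if dt <= 0 or dt > 1:
        raise ValueError("dt must lie in (0, 1]")
    year = state.year
    s = state.copy()

    grads = s.medical_students / rates.med_school_duration
    dropout = rates.dropout_rate * s.medical_students
    to_other_res = rates.fraction_other_residency * grads
    to_ho = grads - to_other_res

    ho_attr = rates.ho_attrition * s.house_officers
    mo_attr_rate = rates.mo_attrition(year)
    mo_attr = mo_attr_rate * s.medical_officers
    mo_hiring = min(
        desired_hiring(rates.desired_medical_officers(year), s.medical_officers,
                       mo_attr_rate),
        max(0.0, s.house_officers / dt - ho_attr),
    )

    # Residency intake drawn from house officers first, then medical officers.
    intake_demanded = max(0.0, rates.residency_intake(year))
    ho_capacity = max(0.0, s.house_officers / dt - ho_attr - mo_hiring)
    intake_ho = min(intake_demanded, ho_capacity)
    mo_capacity = max(0.0, s.medical_officers / dt - mo_attr)
    intake_mo = min(intake_demanded - intake_ho, mo_capacity)
    intake = intake_ho + intake_mo

    oph_attr = rates.oph_attrition * s.ophthalmologists

    s.medical_students += (rates.admissions(year) - dropout - grads) * dt
    s.house_officers += (to_ho - ho_attr - mo_hiring - intake_ho) * dt
    s.medical_officers += (mo_hiring - mo_attr - intake_mo) * dt
    s.residents[0] += intake * dt
    s.ophthalmologists += -oph_attr * dt

    inflow = rates.admissions(year) * dt
    outflow = (dropout + to_other_res + ho_attr + mo_attr + oph_attr) * dt

    s.year = year + dt
    if abs(s.year - round(s.year)) < 1e-9:
        s.year = round(s.year)
        graduates = float(s.residents[-1])
        hired = min(graduates, max(0.0, hires_demanded))
        surplus = graduates - hired
        s.residents[1:] = s.residents[:-1]
        s.residents[0] = 0.0
        s.ophthalmologists += hired
        outflow += surplus

    # Numerical guard: tiny negative stocks from Euler overshoot are floored.
    for name in ("medical_students", "house_officers", "medical_officers",
                 "ophthalmologists"):
        setattr(s, name, max(0.0, getattr(s, name)))
    np.clip(s.residents, 0.0, None, out=s.residents)

    if not return_audit:
        return s
    audit = PipelineAudit(inflow, outflow, state.total(), s.total())
    return s, audit


def steady_pipeline_state(
    rates: PipelineRates, year: float, ophthalmologists: float, intake: float | None = None
) -> WorkforceState:
    """A pipeline state pre-filled at the analytic steady state of its flows."""
    admissions = rates.admissions(year)
    students = admissions * rates.med_school_duration / (
        1.0 + rates.dropout_rate * rates.med_school_duration)
    grads = students / rates.med_school_duration
    to_ho = grads * (1.0 - rates.fraction_other_residency)
    if intake is None:
        intake = rates.residency_intake(year)
    ho = max(0.0, (to_ho - intake) / max(rates.ho_attrition, 1e-9))
    mo = rates.desired_medical_officers(year)
    chain = np.full(rates.residency_duration, intake, dtype=float)
    return WorkforceState(year, students, ho, mo, chain, ophthalmologists)


def simulate_supply(
    initial_supply: float,
    rates: PipelineRates,
    intake: float,
    required: Sequence[float],
    prefill: bool = True,
) -> np.ndarray:
    """Annual ophthalmologist supply under a constant residency intake.

    A reduced supply-only simulation used for intake planning: the
    residency chain (pre-filled at the candidate intake unless ``prefill``
    is false) feeds graduates once a year; hiring is capped by desired
    hiring against the required trajectory; attrition is applied annually.
    """
    duration = rates.residency_duration
    chain = np.full(duration, intake if prefill else 0.0, dtype=float)
    oph = float(initial_supply)
    supply = np.empty(len(required), dtype=float)
    for t, req in enumerate(required):
        hires_demanded = desired_hiring(req, oph, rates.oph_attrition)
        graduates = chain[-1]
        hired = min(graduates, hires_demanded)
        oph = oph * (1.0 - rates.oph_attrition) + hired
        chain[1:] = chain[:-1]
        chain[0] = intake
        supply[t] = oph
    return supply


def _intake_meets(
    intake: float,
    initial_supply: float,
    rates: PipelineRates,
    required: np.ndarray,
    slack: float,
) -> bool:
    supply = simulate_supply(initial_supply, rates, intake, required)
    if supply[-1] < required[-1] - 1e-9:
        return False
    return bool(np.all(supply >= required - slack - 1e-9))


def plan_required_intake(
    required_trajectories: Sequence[Sequence[float]],
    rates: PipelineRates,
    initial_supply: float,
    bounds: tuple[int, int] = (0, 200),
    slack: float | None = None,
) -> tuple[int, int]:
    """Annual residency intake interval covering demand uncertainty.

    For each required-headcount trajectory (typically the lower and upper
    credible bounds of the demand projection), finds by bisection the
    smallest constant integer intake whose simulated supply meets the
    trajectory at the horizon and never undershoots it by more than
    ``slack`` (default: 10% of the trajectory maximum) mid-horizon.
    Returns the (min, max) over trajectories, mirroring the per-scenario
    intake ranges planners work with.
    """
    lo_bound, hi_bound = bounds
    results = []
    for traj in required_trajectories:
        required = np.asarray(traj, dtype=float)
        if required.size <= rates.residency_duration:
            raise ValueError("trajectory must span beyond the residency duration")
        s = 0.1 * float(required.max()) if slack is None else slack
        if not _intake_meets(hi_bound, initial_supply, rates, required, s):
            raise InfeasibleIntakeError(
                f"intake {hi_bound} cannot meet the required trajectory")
        lo, hi = lo_bound, hi_bound  # invariant: hi feasible, lo-1 unknown/infeasible
        while lo < hi:
            mid = (lo + hi) // 2
            if _intake_meets(mid, initial_supply, rates, required, s):
                hi = mid
            else:
                lo = mid + 1
        results.append(hi)
    return min(results), max(results)
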