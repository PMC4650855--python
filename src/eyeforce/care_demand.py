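"""Patients in public-sector specialist care and the visits they generate.

Two stocks are tracked per condition on the adult (40+) grid: patients in
care and — for the three conditions with a finite course of treatment
(cataract, myopia, refractive error) — people who have completed care.
New patients arrive from the untreated prevalent pool at education-specific
uptake rates; a condition-specific fraction of new patients may be decanted
to community primary eyecare clinics and leaves specialist demand; patients
in care exit by completing treatment (stock / average duration) or by
death at age-specific mortality; survivors age along the cohort chain with
an absorbing 100+ bin.  Annual visit demand is patients in care times the
average visits per patient per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .dimensions import (
    CARE_SHAPE,
    CONDITIONS,
    CONDITION_INDEX,
    CURABLE_DURATIONS,
    CURABLE_INDICES,
    EDUCATIONS,
    N_CONDITIONS,
)

__all__ = [
    "CareParameters",
    "CareState",
    "CareStepAudit",
    "untreated_pool",
    "new_patient_flow",
    "split_decant",
    "completion_flow",
    "step_care",
    "demand_visits",
    "initialize_care_state",
    "equilibrium_care_state",
    "collapse_ethnicity",
]

#: Baseline education-specific uptake factors (per year), estimated by
#: calibration in the source data and used as the package defaults.
DEFAULT_UPTAKE = {"none": 0.045, "primary": 0.07, "secondary": 0.076, "tertiary": 0.15}

#: Case-mix fractions of patients in care, from administrative records.
DEFAULT_CASE_MIX = {
    "cataract": 0.31,
    "dr": 0.09,
    "glaucoma": 0.17,
    "amd": 0.03,
    "myopia": 0.02,
    "refractive_error": 0.02,
    "erm": 0.01,
    "rvo": 0.01,
    "other": 0.34,
}

UptakeValue = float | Callable[[float], float]


def _value_at(v: UptakeValue, year: float) -> float:
    return float(v(year)) if callable(v) else float(v)


@dataclass
class CareParameters:
    """Uptake, treatment-duration, case-mix, visit-rate and decant parameters.

    ``uptake`` maps education stratum to a per-year rate (or a callable of
    calendar year, used for scenario ramps).  ``decant_fraction`` maps
    condition to the fraction of *new* patients diverted to primary eyecare
    clinics (also possibly time-varying).
    """

    uptake: Mapping[str, UptakeValue] = field(
        default_factory=lambda: dict(DEFAULT_UPTAKE))
    duration_in_care: Mapping[str, float] = field(
        default_factory=lambda: dict(CURABLE_DURATIONS))
    visits_per_patient_year: float | Mapping[str, float] = 2.4
    case_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CASE_MIX))
    completed_init_fraction: float = 0.1
    decant_fraction: Mapping[str, UptakeValue] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(sum(self.case_mix.values()) - 1.0) > 1e-9:
            raise ValueError("case_mix must sum to 1")
        if any(d <= 0 for d in self.duration_in_care.values()):
            raise ValueError("durations in care must be positive")
        if set(self.duration_in_care) != set(CURABLE_DURATIONS):
            raise ValueError("durations apply exactly to the curable conditions")

    def uptake_at(self, year: float) -> np.ndarray:
        """Uptake per education stratum at a calendar year, validated to [0,1]."""
        rates = np.array([_value_at(self.uptake[e], year) for e in EDUCATIONS])
        if np.any(rates < 0) or np.any(rates > 1):
            raise ValueError("uptake factors must lie in [0, 1]")
        return rates

    def decant_at(self, year: float) -> np.ndarray:
        """Decant fraction per condition at a calendar year."""
        fractions = np.array(
            [_value_at(self.decant_fraction.get(c, 0.0), year) for c in CONDITIONS]
        )
        if np.any(fractions < 0) or np.any(fractions > 1):
            raise ValueError("decant fractions must lie in [0, 1]")
        return fractions

    def visit_rates(self) -> np.ndarray:
        """Visits per patient per year, per condition."""
        v = self.visits_per_patient_year
        if isinstance(v, Mapping):
            rates = np.array([float(v[c]) for c in CONDITIONS])
        else:
            rates = np.full(N_CONDITIONS, float(v))
        if np.any(rates <= 0):
            raise ValueError("visits per patient-year must be positive")
        return rates

    def completion_rates(self) -> np.ndarray:
        """Per-condition completion rate 1/duration (0 for lifelong care)."""
        rates = np.zeros(N_CONDITIONS)
        for c, d in self.duration_in_care.items():
            rates[CONDITION_INDEX[c]] = 1.0 / d
        return rates


@dataclass
class CareState:
    """In-care and completed-care stocks by condition x adult age x education."""

    year: float
    in_care: np.ndarray
    completed: np.ndarray

    def __post_init__(self) -> None:
        for name in ("in_care", "completed"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != CARE_SHAPE:
                raise ValueError(f"{name} must have shape {CARE_SHAPE}")
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite and non-negative")
            setattr(self, name, arr)

    def copy(self) -> "CareState":
        return CareState(self.year, self.in_care.copy(), self.completed.copy())

    def patients(self) -> float:
        return float(self.in_care.sum())


@dataclass
class CareStepAudit:
    """Per-condition stock balance of one Euler step."""

    inflow: np.ndarray        # per condition, patients/year
    completion: np.ndarray
    deaths: np.ndarray        # in-care deaths per condition, patients/year
    dt: float
    old_stock: np.ndarray
    new_stock: np.ndarray

    @property
    def imbalance(self) -> float:
        """Max relative balance error over conditions (before aging shift)."""
        expected = (self.inflow - self.completion - self.deaths) * self.dt
        scale = np.maximum(np.abs(self.old_stock), 1.0)
        return float(np.max(np.abs((self.new_stock - self.old_stock) - expected) / scale))


def collapse_ethnicity(prevalent: np.ndarray) -> np.ndarray:
    """Marginalize the ethnicity axis of a prevalent-cases array."""
    return prevalent.sum(axis=2)


def untreated_pool(prevalent: np.ndarray, state: CareState) -> np.ndarray:
    """People with a condition who are neither in care nor treated.

    ``prevalent`` is by condition x adult age x education (ethnicity already
    marginalized).  The completed-care subtraction applies only to the
    curable conditions; the pool is clamped at zero because uptake also
    absorbs groups (foreigners, under-40s) outside the prevalent base.
    """
    if prevalent.shape != CARE_SHAPE:
        raise ValueError(f"prevalent must have shape {CARE_SHAPE}")
    return np.clip(prevalent - state.in_care - state.completed, 0.0, None)


def new_patient_flow(
    untreated: np.ndarray, params: CareParameters, year: float
) -> np.ndarray:
    """New patients seeking care per year: uptake[education] x untreated."""
    return untreated * params.uptake_at(year)[None, None, :]


def split_decant(
    new_patients: np.ndarray, params: CareParameters, year: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split the new-patient flow into specialist (SOC) and community (PEC) parts.

    Returns ``(soc_flow, pec_flow)``; their sum is the input flow exactly.
    """
    d = params.decant_at(year)[:, None, None]
    pec = new_patients * d
    return new_patients - pec, pec


def completion_flow(state: CareState, params: CareParameters) -> np.ndarray:
    """Patients completing treatment per year: in-care / duration (curable only)."""
    return state.in_care * params.completion_rates()[:, None, None]


def _shift_adult_cohorts(arr: np.ndarray) -> np.ndarray:
    shifted = np.empty_like(arr)
    shifted[:, -1] = arr[:, -1] + arr[:, -2]
    shifted[:, 1:-1] = arr[:, :-2]
    shifted[:, 0] = 0.0
    return shifted


def step_care(
    state: CareState,
    soc_flow: np.ndarray,
    completion: np.ndarray,
    death_rates: np.ndarray,
    dt: float,
    return_audit: bool = False,
) -> CareState | tuple[CareState, CareStepAudit]:
    """Advance the care stocks by one Euler step of length ``dt`` years.

    ``death_rates`` is mortality per year by adult age (applied to both
    stocks).  On a whole-year boundary both stocks age one cohort, with the
    100+ bin absorbing.
    """
    if dt <= 0 or dt > 1:
        raise ValueError("dt must lie in (0, 1]")
    mu = np.asarray(death_rates, dtype=float)[None, :, None]
    in_deaths = mu * state.in_care
    done_deaths = mu * state.completed

    in_care = state.in_care + (soc_flow - completion - in_deaths) * dt
    completed = state.completed + (completion - done_deaths) * dt
    np.clip(in_care, 0.0, None, out=in_care)
    np.clip(completed, 0.0, None, out=completed)

    audit = None
    if return_audit:
        audit = CareStepAudit(
            inflow=soc_flow.sum(axis=(1, 2)),
            completion=completion.sum(axis=(1, 2)),
            deaths=in_deaths.sum(axis=(1, 2)),
            dt=dt,
            old_stock=state.in_care.sum(axis=(1, 2)),
            new_stock=in_care.sum(axis=(1, 2)),
        )

    year = state.year + dt
    if abs(year - round(year)) < 1e-9:
        year = round(year)
        in_care = _shift_adult_cohorts(in_care)
        completed = _shift_adult_cohorts(completed)
    new_state = CareState(year, in_care, completed)
    return (new_state, audit) if return_audit else new_state


def demand_visits(
    state: CareState, params: CareParameters
) -> tuple[float, pd.Series]:
    """Annual visit demand, total and by condition."""
    per_condition = state.in_care.sum(axis=(1, 2)) * params.visit_rates()
    series = pd.Series(per_condition, index=pd.Index(CONDITIONS, name="condition"))
    return float(per_condition.sum()), series


def initialize_care_state(
    base_demand: float,
    params: CareParameters,
    prevalent: np.ndarray,
    year: float,
) -> CareState:
    """Seed the care stocks from an observed base-year visit volume.

    Total patients are ``base_demand / visits_per_patient_year``, split
    across conditions by the case mix and, within a condition, across
    age/education cells proportionally to the prevalent pool (a stratum
    with no prevalent cases receives none).  Completed-care stocks start
    at ``completed_init_fraction`` of the in-care stock for the curable
    conditions.
    """
    if base_demand <= 0:
        raise ValueError("base_demand must be positive")
    if prevalent.shape != CARE_SHAPE:
        raise ValueError(f"prevalent must have shape {CARE_SHAPE}")
    visit_rates = params.visit_rates()
    if isinstance(params.visits_per_patient_year, Mapping):
        # With per-condition rates, patients follow from case-mix visit shares.
        mean_rate = float(
            sum(params.case_mix[c] * visit_rates[CONDITION_INDEX[c]] for c in CONDITIONS)
        )
    else:
        mean_rate = float(visit_rates[0])
    total_patients = base_demand / mean_rate

    in_care = np.zeros(CARE_SHAPE)
    overall = prevalent.sum(axis=0)
    for c in CONDITIONS:
        i = CONDITION_INDEX[c]
        n_c = total_patients * params.case_mix[c]
        weights = prevalent[i]
        wsum = weights.sum()
        if wsum <= 0:
            # No condition-specific pool: fall back on the overall prevalent shape.
            weights, wsum = overall, overall.sum()
        if wsum <= 0:
            raise ValueError("cannot allocate patients: prevalent pool is empty")
        in_care[i] = n_c * weights / wsum

    completed = np.zeros(CARE_SHAPE)
    for i in CURABLE_INDICES:
        completed[i] = params.completed_init_fraction * in_care[i]
    return CareState(year, in_care, completed)


def equilibrium_care_state(
    prevalent: np.ndarray,
    params: CareParameters,
    death_rates: np.ndarray,
    year: float,
) -> CareState:
    """Care stocks at the fixed point implied by a frozen prevalent pool.

    Solves, per cell, the stationarity of the in-care/completed system
    under uptake ``u``, completion rate ``r`` and mortality ``mu``:
    ``u (P - I - C) = (r + mu) I`` and ``r I = mu C``.  Useful for
    starting mechanism studies at equilibrium so initialization
    transients do not confound growth-rate comparisons.
    """
    u = params.uptake_at(year)[None, None, :]
    r = params.completion_rates()[:, None, None]
    mu = np.asarray(death_rates, dtype=float)[None, :, None]
    mu = np.maximum(mu, 1e-12)
    # From the two balance equations: I = u P / (u (1 + r/mu) + r + mu).
    in_care = u * prevalent / (u * (1.0 + r / mu) + r + mu)
    completed = r * in_care / mu
    return CareState(year, in_care, completed)
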