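"""Named policy scenarios and the end-to-end projection runner.

Four scenarios span the policy space:

* ``business_as_usual`` — uptake factors frozen at their calibrated
  baseline values; 5% of new patients with DR, glaucoma, myopia and
  refractive error decanted to community primary eyecare clinics.
* ``current_policy`` — uptake ramps linearly from the baseline (at 2013)
  to higher 2040 endpoints reflecting increased screening, awareness and
  access (none 13%, primary 20%, secondary 21%, tertiary 46%).
* ``new_model_of_care`` — as current policy, but 20% of new DR and
  glaucoma patients and 90% of new myopia and refractive-error patients
  are decanted to community clinics.
* ``moderated_workload`` — as new model of care, with a 15% reduction in
  the clinical workload of ophthalmologists.

Scenario overrides start at the ramp year (2013); before it all
scenarios coincide exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from . import care_demand as cd
from . import demography as dg
from . import prevalence as pv
from . import workforce as wf
from .dimensions import ADULT_MIN_AGE, CONDITIONS, EDUCATIONS

__all__ = [
    "ScenarioSpec",
    "ScenarioRun",
    "SCENARIO_NAMES",
    "build_scenario",
    "value_at",
    "run_scenario",
    "run_all_scenarios",
]

SCENARIO_NAMES = (
    "business_as_usual",
    "current_policy",
    "new_model_of_care",
    "moderated_workload",
)

_BASE_UPTAKE = dict(cd.DEFAULT_UPTAKE)
_RAISED_UPTAKE = {"none": 0.13, "primary": 0.20, "secondary": 0.21, "tertiary": 0.46}
_BAU_DECANT = {"dr": 0.05, "glaucoma": 0.05, "myopia": 0.05, "refractive_error": 0.05}
_NMC_DECANT = {"dr": 0.20, "glaucoma": 0.20, "myopia": 0.90, "refractive_error": 0.90}


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameter trajectories overriding the baseline model."""

    name: str
    uptake_start: Mapping[str, float] = field(default_factory=lambda: dict(_BASE_UPTAKE))
    uptake_end: Mapping[str, float] | None = None
    decant_fractions: Mapping[str, float] = field(default_factory=dict)
    workload_multiplier: float = 1.0
    ramp_start: float = 2013.0
    ramp_end: float = 2040.0

    def __post_init__(self) -> None:
        if self.ramp_start >= self.ramp_end:
            raise ValueError("ramp start year must precede end year")
        pools = [self.uptake_start.values(), self.decant_fractions.values()]
        if self.uptake_end is not None:
            pools.append(self.uptake_end.values())
        for pool in pools:
            if any(not (0.0 <= v <= 1.0) for v in pool):
                raise ValueError("scenario fractions must lie in [0, 1]")


def build_scenario(name: str) -> ScenarioSpec:
    """The four named scenarios; unknown names raise ``ValueError``."""
    if name == "business_as_usual":
        return ScenarioSpec(name, decant_fractions=dict(_BAU_DECANT))
    if name == "current_policy":
        return ScenarioSpec(name, uptake_end=dict(_RAISED_UPTAKE),
                            decant_fractions=dict(_BAU_DECANT))
    if name == "new_model_of_care":
        return ScenarioSpec(name, uptake_end=dict(_RAISED_UPTAKE),
                            decant_fractions=dict(_NMC_DECANT))
    if name == "moderated_workload":
        return ScenarioSpec(name, uptake_end=dict(_RAISED_UPTAKE),
                            decant_fractions=dict(_NMC_DECANT),
                            workload_multiplier=0.85)
    raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")


def value_at(spec: ScenarioSpec, parameter: str | tuple[str, str], year: float) -> float:
    """Scenario parameter value at a calendar year.

    Uptake ramps interpolate linearly between the baseline value at the
    ramp start and the scenario endpoint at the ramp end (constant
    outside); decant fractions and the workload multiplier switch on as
    step functions at the ramp start.
    """
    if parameter == "workload_multiplier":
        return spec.workload_multiplier if year >= spec.ramp_start else 1.0
    kind, key = parameter
    if kind == "uptake":
        v0 = spec.uptake_start[key]
        if spec.uptake_end is None:
            return v0
        v1 = spec.uptake_end[key]
        if year <= spec.ramp_start:
            return v0
        if year >= spec.ramp_end:
            return v1
        frac = (year - spec.ramp_start) / (spec.ramp_end - spec.ramp_start)
        return v0 + frac * (v1 - v0)
    if kind == "decant":
        if year < spec.ramp_start:
            return 0.0
        return spec.decant_fractions.get(key, 0.0)
    raise ValueError(f"unknown parameter {parameter!r}")


def scenario_care_parameters(spec: ScenarioSpec, base: cd.CareParameters) -> cd.CareParameters:
    """Baseline care parameters with the scenario's trajectories patched in.

    Uptake ramps anchor at the *baseline model's* uptake values (e.g. a
    calibrated or posterior-drawn vector), so a scenario describes the
    policy change relative to whatever baseline it is run against.
    """

    def make_uptake(e: str):
        u0 = base.uptake[e]
        u0 = float(u0(spec.ramp_start)) if callable(u0) else float(u0)
        u1 = u0 if spec.uptake_end is None else float(spec.uptake_end[e])

        def ramp(year: float, u0: float = u0, u1: float = u1) -> float:
            if year <= spec.ramp_start:
                return u0
            if year >= spec.ramp_end:
                return u1
            frac = (year - spec.ramp_start) / (spec.ramp_end - spec.ramp_start)
            return u0 + frac * (u1 - u0)

        return ramp

    uptake = {e: make_uptake(e) for e in EDUCATIONS}
    decant = {
        c: (lambda year, c=c: value_at(spec, ("decant", c), year)) for c in CONDITIONS
    }
    return replace(base, uptake=uptake, decant_fraction=decant)


class ModelInputs(Protocol):
    """What the runner needs; satisfied by :class:`~eyeforce.synthetic_data.SyntheticWorld`."""

    base_year: int
    base_population: dg.PopulationState
    demographic_inputs: dg.DemographicInputs
    prevalence_table: pv.PrevalenceTable
    care_params: cd.CareParameters
    pipeline_rates: wf.PipelineRates
    workload_model: wf.WorkloadModel
    base_demand_visits: float


@dataclass
class ScenarioRun:
    """Annual outputs of one end-to-end scenario projection."""

    scenario: str
    years: np.ndarray
    population_total: pd.Series
    population_40plus: pd.Series
    prevalent_cases: pd.DataFrame          # condition x year
    demand: pd.Series                      # visits/year
    demand_by_condition: pd.DataFrame      # condition x year
    patients_in_care: pd.Series
    pec_diverted: pd.Series                # new patients/year diverted to PECs
    required: pd.Series                    # continuous headcount
    required_reported: pd.Series           # rounded up for reporting
    supply: pd.Series
    max_population_imbalance: float
    max_care_imbalance: float
    max_pipeline_imbalance: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format (year, scenario, output, value) table."""
        rows = []
        for name, series in [
            ("population_total", self.population_total),
            ("population_40plus", self.population_40plus),
            ("demand_visits", self.demand),
            ("patients_in_care", self.patients_in_care),
            ("pec_diverted", self.pec_diverted),
            ("required_ophthalmologists", self.required),
            ("supplied_ophthalmologists", self.supply),
        ]:
            for year, value in series.items():
                rows.append((int(year), self.scenario, name, float(value)))
        return pd.DataFrame(rows, columns=["year", "scenario", "output", "value"])


def run_scenario(
    spec: ScenarioSpec,
    inputs: ModelInputs,
    horizon: int = 2040,
    dt: float = 0.25,
    population_trajectory: Sequence[dg.PopulationState] | None = None,
    collect_audits: bool = False,
) -> ScenarioRun:
    """Deterministic end-to-end projection under one scenario.

    Wires demography -> prevalence -> care demand -> workforce at annual
    output resolution; the population projection is scenario-independent
    and may be passed in precomputed.
    """
    base_year = inputs.base_year
    n_sub = round(1.0 / dt)
    if abs(n_sub * dt - 1.0) > 1e-9:
        raise ValueError("1/dt must be an integer")

    pop_audits: list[dg.StepAudit] | None = [] if collect_audits else None
    if population_trajectory is None:
        population_trajectory = dg.project_population(
            inputs.demographic_inputs, inputs.base_population, horizon, dt,
            collect_audits=pop_audits)
    pop_by_year = {int(round(s.year)): s for s in population_trajectory}
    years = np.arange(base_year, horizon + 1)

    prev_by_year = {
        y: cd.collapse_ethnicity(pv.prevalent_all(pop_by_year[y], inputs.prevalence_table, y))
        for y in years
    }
    params = scenario_care_parameters(spec, inputs.care_params)
    care = cd.initialize_care_state(
        inputs.base_demand_visits, params, prev_by_year[base_year], base_year)

    workload = replace(inputs.workload_model,
                       workload_multiplier=lambda yr: value_at(spec, "workload_multiplier", yr))
    req0, _ = wf.required_ophthalmologists(inputs.base_demand_visits, workload, base_year)
    pipe = wf.steady_pipeline_state(inputs.pipeline_rates, base_year, ophthalmologists=req0)

    demand_s, patients_s, pec_s, req_s, req_rep_s, supply_s = {}, {}, {}, {}, {}, {}
    demand_by_cond = {}
    max_care_imb = 0.0
    max_pipe_imb = 0.0

    def record(year: int) -> None:
        total, by_cond = cd.demand_visits(care, params)
        demand_s[year] = total
        demand_by_cond[year] = by_cond
        patients_s[year] = care.patients()
        req, req_rep = wf.required_ophthalmologists(total, workload, year)
        req_s[year], req_rep_s[year] = req, req_rep
        supply_s[year] = pipe.ophthalmologists

    record(base_year)
    pec_s[base_year] = 0.0
    t = float(base_year)
    for year in years[:-1]:
        pec_year = 0.0
        for _ in range(n_sub):
            prev = prev_by_year[int(np.floor(t + 1e-9))]
            untreated = cd.untreated_pool(prev, care)
            flow = cd.new_patient_flow(untreated, params, t)
            soc, pec = cd.split_decant(flow, params, t)
            completion = cd.completion_flow(care, params)
            mu = inputs.demographic_inputs.death_rate.at(t)[ADULT_MIN_AGE:]
            if collect_audits:
                care, care_audit = cd.step_care(care, soc, completion, mu, dt,
                                                return_audit=True)
                max_care_imb = max(max_care_imb, care_audit.imbalance)
            else:
                care = cd.step_care(care, soc, completion, mu, dt)
            pec_year += float(pec.sum()) * dt

            visits_now, _ = cd.demand_visits(care, params)
            req_now, _ = wf.required_ophthalmologists(visits_now, workload, t)
            hires = wf.desired_hiring(req_now, pipe.ophthalmologists,
                                      inputs.pipeline_rates.oph_attrition)
            if collect_audits:
                pipe, pipe_audit = wf.step_pipeline(pipe, inputs.pipeline_rates, hires,
                                                    dt, return_audit=True)
                max_pipe_imb = max(max_pipe_imb, pipe_audit.imbalance)
            else:
                pipe = wf.step_pipeline(pipe, inputs.pipeline_rates, hires, dt)
            t += dt
        t = round(t)
        record(int(t))
        pec_s[int(t)] = pec_year

    prevalent = pv.prevalence_projection_table(
        population_trajectory, inputs.prevalence_table, list(years))
    pop_total = pd.Series({y: pop_by_year[y].total() for y in years})
    pop_40 = pd.Series(
        {y: float(pop_by_year[y].counts[ADULT_MIN_AGE:].sum()) for y in years})
    max_pop_imb = max((a.imbalance for a in pop_audits), default=0.0) if pop_audits else 0.0

    return ScenarioRun(
        scenario=spec.name,
        years=years,
        population_total=pop_total,
        population_40plus=pop_40,
        prevalent_cases=prevalent,
        demand=pd.Series(demand_s),
        demand_by_condition=pd.DataFrame(demand_by_cond),
        patients_in_care=pd.Series(patients_s),
        pec_diverted=pd.Series(pec_s),
        required=pd.Series(req_s),
        required_reported=pd.Series(req_rep_s),
        supply=pd.Series(supply_s),
        max_population_imbalance=max_pop_imb,
        max_care_imbalance=max_care_imb,
        max_pipeline_imbalance=max_pipe_imb,
    )


def run_all_scenarios(
    inputs: ModelInputs,
    horizon: int = 2040,
    dt: float = 0.25,
    names: Sequence[str] = SCENARIO_NAMES,
    collect_audits: bool = False,
) -> dict[str, ScenarioRun]:
    """Run every named scenario on shared inputs (population computed once)."""
    trajectory = dg.project_population(
        inputs.demographic_inputs, inputs.base_population, horizon, dt)
    return {
        name: run_scenario(build_scenario(name), inputs, horizon, dt,
                           population_trajectory=trajectory,
                           collect_audits=collect_audits)
        for name in names
    }
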