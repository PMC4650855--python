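"""Reproducibility studies: the package's headline checks, run end to end.

Each function regenerates its inputs from a seed, runs the relevant part
of the pipeline and returns measured quantities — conservation audits,
scaling laws, scenario orderings, pipeline analytics, calibration
recovery and coverage, and the aging-mechanism comparison.  The worked
examples recompute the published percent changes and scenario ratios
from the published central projection figures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calibration as cal
from . import published
from . import report as rp
from . import scenarios as sc
from . import synthetic_data as sd
from . import workforce as wf
from .dimensions import EDUCATIONS

__all__ = [
    "worked_examples",
    "conservation_study",
    "workload_scaling_study",
    "ordering_study",
    "pipeline_study",
    "recovery_study",
    "coverage_study",
    "aging_mechanism_study",
]


def worked_examples() -> dict[str, float]:
    """Percent changes and ratios recomputed from the published table cells."""
    prev = published.PREVALENCE_CASES
    demand = published.DEMAND_VISITS
    oph = published.REQUIRED_OPHTHALMOLOGISTS
    out = {
        "pct_change_prevalence_dr": rp.percent_change(prev.loc["dr", 2015],
                                                      prev.loc["dr", 2040]),
        "pct_change_prevalence_glaucoma": rp.percent_change(
            prev.loc["glaucoma", 2015], prev.loc["glaucoma", 2040]),
        "pct_change_prevalence_erm": rp.percent_change(prev.loc["erm", 2015],
                                                       prev.loc["erm", 2040]),
        "pct_change_prevalence_cataract": rp.percent_change(
            prev.loc["cataract", 2015], prev.loc["cataract", 2040]),
        "pct_change_prevalence_myopia": rp.percent_change(
            prev.loc["myopia", 2015], prev.loc["myopia", 2040]),
        "pct_change_demand_bau": rp.percent_change(
            demand.loc["business_as_usual", 2015],
            demand.loc["business_as_usual", 2040]),
        "pct_change_demand_current_policy": rp.percent_change(
            demand.loc["current_policy", 2015],
            demand.loc["current_policy", 2040]),
        "pct_change_demand_new_model": rp.percent_change(
            demand.loc["new_model_of_care", 2015],
            demand.loc["new_model_of_care", 2040]),
        "pct_change_ophthalmologists_current_policy": rp.percent_change(
            oph.loc["current_policy", 2015], oph.loc["current_policy", 2040]),
        "ratio_current_policy_vs_bau_2040": rp.scenario_ratio(
            oph.loc["current_policy", 2040], oph.loc["business_as_usual", 2040]),
        "ratio_new_model_vs_bau_2040": rp.scenario_ratio(
            oph.loc["new_model_of_care", 2040], oph.loc["business_as_usual", 2040]),
        "ratio_moderated_vs_bau_2040": rp.scenario_ratio(
            oph.loc["moderated_workload", 2040], oph.loc["business_as_usual", 2040]),
    }
    return {k: float(v) for k, v in out.items()}


def conservation_study(seed: int) -> dict[str, float]:
    """Max relative stock-balance error over every step of a 2010-2040 run."""
    world = sd.generate_world(seed)
    runs = sc.run_all_scenarios(world, collect_audits=True)
    return {
        "max_population_imbalance": max(
            r.max_population_imbalance for r in runs.values()),
        "max_care_imbalance": max(r.max_care_imbalance for r in runs.values()),
        "max_pipeline_imbalance": max(
            r.max_pipeline_imbalance for r in runs.values()),
    }


def workload_scaling_study(seed: int) -> dict[str, float]:
    """Moderated-workload vs new-model runs on identical inputs.

    Demand must be identical; the pre-rounding requirement ratio must be
    1/0.85 everywhere the multiplier is active.
    """
    world = sd.generate_world(seed)
    runs = sc.run_all_scenarios(
        world, names=("new_model_of_care", "moderated_workload"))
    nmc, mw = runs["new_model_of_care"], runs["moderated_workload"]
    demand_gap = float(np.max(np.abs(mw.demand.to_numpy() - nmc.demand.to_numpy())))
    ratio = (mw.required.loc[2013:] / nmc.required.loc[2013:]).to_numpy()
    return {
        "max_abs_demand_difference": demand_gap,
        "requirement_ratio_max_error": float(np.max(np.abs(ratio - 1.0 / 0.85))),
    }


def ordering_study(seeds: list[int]) -> dict[str, float]:
    """Scenario ordering at 2040 across independent synthetic worlds."""
    passed = 0
    for seed in seeds:
        world = sd.generate_world(seed)
        runs = sc.run_all_scenarios(world)
        bau, cp = runs["business_as_usual"], runs["current_policy"]
        nmc, mw = runs["new_model_of_care"], runs["moderated_workload"]
        ok = (bau.demand[2040] <= cp.demand[2040] + 1e-9
              and nmc.demand[2040] <= cp.demand[2040] + 1e-9
              and mw.required[2040] >= nmc.required[2040] - 1e-9)
        passed += bool(ok)
    return {"ordering_pass_count": passed, "ordering_seed_count": len(seeds)}


def pipeline_study() -> dict[str, float]:
    """Analytic pipeline checks: steady state, training delay, intake planning."""
    from .timeseries import YearPath

    rates = wf.PipelineRates(
        admissions=YearPath.constant(100.0),
        desired_medical_officers=YearPath.constant(0.0),
        residency_intake=YearPath.constant(9.0),
    )
    state = wf.steady_pipeline_state(rates, 2000.0, ophthalmologists=0.0)
    for _ in range(150 * 4):
        state = wf.step_pipeline(state, rates, hires_demanded=1e9, dt=0.25)
    steady_rel_err = abs(state.ophthalmologists - 9.0 / 0.03) / (9.0 / 0.03)

    pulse_rates = wf.PipelineRates(
        admissions=YearPath.constant(100.0),
        desired_medical_officers=YearPath.constant(0.0),
        residency_intake=lambda year: 5.0 if 2010 <= year < 2011 else 0.0,
        oph_attrition=0.0,
    )
    pulse_state = wf.WorkforceState(2010.0, 500.0, 100.0, 0.0, np.zeros(5), 50.0)
    early_response = 0.0
    delayed_response = 0.0
    for _ in range(4 * 7):
        pulse_state = wf.step_pipeline(pulse_state, pulse_rates,
                                       hires_demanded=1e9, dt=0.25)
        change = pulse_state.ophthalmologists - 50.0
        if pulse_state.year < 2015:
            early_response = max(early_response, abs(change))
        else:
            delayed_response = max(delayed_response, change)

    plan_cases = [
        (100.0, np.linspace(100, 280, 30), 0.03),
        (100.0, np.linspace(100, 250, 25), 0.00),
        (50.0, np.linspace(60, 200, 30), 0.05),
        (200.0, np.linspace(210, 300, 35), 0.03),
        (80.0, 80.0 + 6.0 * np.arange(30), 0.03),
    ]
    matches = 0
    for initial, required, attrition in plan_cases:
        case_rates = wf.PipelineRates(
            admissions=YearPath.constant(100.0),
            desired_medical_officers=YearPath.constant(0.0),
            oph_attrition=attrition,
        )
        slack = 0.1 * float(np.max(required))
        scan = next(k for k in range(0, 61)
                    if wf._intake_meets(k, initial, case_rates, required, slack))
        lo, hi = wf.plan_required_intake([required], case_rates, initial,
                                         bounds=(0, 60))
        matches += int(lo == hi == scan)
    return {
        "steady_state_rel_err": float(steady_rel_err),
        "pre_delay_supply_response": float(early_response),
        "post_delay_supply_response": float(delayed_response),
        "intake_plan_scan_matches": matches,
        "intake_plan_cases": len(plan_cases),
    }


def _calibrate(world: sd.SyntheticWorld, n_iterations: int, seed: int):
    problem = cal.CalibrationProblem(
        world.observed_history[list(EDUCATIONS)], noise_sd=world.noise_sd)
    sim = cal.UptakeDemandSimulator(
        world, world.observed_history.index,
        population_trajectory=world.population_trajectory(
            int(world.observed_history.index.max())))
    sample = cal.run_mcmc(problem, sim, n_iterations=n_iterations, seed=seed)
    return problem, sim, sample


def recovery_study(seed: int, n_iterations: int = 1500) -> dict[str, float]:
    """Re-estimate the generating uptake factors from the noisy history."""
    world = sd.generate_world(seed)
    _, _, sample = _calibrate(world, n_iterations, seed=seed + 1)
    truth = np.array([world.true_uptake[e] for e in EDUCATIONS])
    rel_err = np.abs(sample.median() - truth) / truth
    out = {f"uptake_{e}_rel_err": float(r) for e, r in zip(EDUCATIONS, rel_err)}
    out["max_uptake_rel_err"] = float(rel_err.max())
    out["acceptance_rate"] = float(sample.acceptance_rate)
    return out


def coverage_study(
    seeds: list[int], n_iterations: int = 1000, max_runs: int = 200
) -> dict[str, float]:
    """Do propagated 95% intervals cover the true-parameter 2040 demand?"""
    covered = 0
    for seed in seeds:
        world = sd.generate_world(seed)
        _, _, sample = _calibrate(world, n_iterations, seed=seed + 1)
        sim_2040 = cal.UptakeDemandSimulator(
            world, [2040], population_trajectory=world.population_trajectory(2040))
        truth = np.array([world.true_uptake[e] for e in EDUCATIONS])
        true_demand = float(sim_2040.series_matrix(truth).sum())

        def runner(params):
            total = float(sim_2040.series_matrix(params).sum())
            return {"demand": pd.Series({2040: total})}

        band = cal.propagate_uncertainty(sample, runner, max_runs=max_runs)["demand"]
        covered += int(band.loc[2040, "lo"] <= true_demand <= band.loc[2040, "hi"])
    return {"coverage_count": covered, "coverage_worlds": len(seeds)}


def aging_mechanism_study(seed: int) -> dict[str, float]:
    """Demand growth vs 40+ head-count growth, with and without age gradient."""
    world = sd.generate_aging_stress_world(seed)
    flat_demand, flat_pop = sd.demand_vs_population_growth(world, flat_prevalence=True)
    grad_demand, grad_pop = sd.demand_vs_population_growth(world, flat_prevalence=False)
    return {
        "flat_prevalence_growth_gap_points": 100.0 * (flat_demand - flat_pop),
        "age_gradient_demand_growth_pct": 100.0 * grad_demand,
        "age_gradient_population_growth_pct": 100.0 * grad_pop,
        "age_gradient_excess_growth_points": 100.0 * (grad_demand - grad_pop),
    }
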