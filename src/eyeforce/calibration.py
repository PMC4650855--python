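"""MCMC calibration of the uptake factors and posterior uncertainty propagation.

The four education-specific uptake factors are the model's most influential
unknowns.  They are calibrated against a historical visit series with a
log-normal observation model (visits are positive; multiplicative error is
the natural choice) and flat priors on [0, 1], sampled with a
component-wise random-walk Metropolis chain whose proposal scales adapt
during burn-in.  Accepted draws after burn-in are re-run through the
scenario model to turn parameter uncertainty into per-year credible
intervals (2.5th/97.5th percentiles of the run outputs).

The production configuration sizes the propagation at 6 000 retained
draws times four scenarios = 24 000 sensitivity model runs; tests and the
desk-scale recovery study use shorter, thinned chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import care_demand as cd
from . import demography as dg
from . import prevalence as pv
from .dimensions import ADULT_MIN_AGE, EDUCATIONS, EDUCATION_INDEX

__all__ = [
    "CalibrationProblem",
    "PosteriorSample",
    "UptakeDemandSimulator",
    "log_posterior",
    "run_mcmc",
    "propagate_uncertainty",
    "geweke_z",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class CalibrationProblem:
    """Observed visit history and the observation-error model.

    ``observed`` is a DataFrame indexed by calendar year.  A single
    ``total`` column calibrates against aggregate visits; columns named
    after education strata calibrate each stratum's series separately
    (which makes the four uptake factors cleanly identifiable).
    ``noise_sd`` is the standard deviation of the observation error on
    the log scale.
    """

    observed: pd.DataFrame
    noise_sd: float = 0.05
    bounds: np.ndarray = field(
        default_factory=lambda: np.tile([0.0, 1.0], (len(EDUCATIONS), 1)))
    parameter_names: tuple[str, ...] = tuple(f"uptake_{e}" for e in EDUCATIONS)

    def __post_init__(self) -> None:
        if isinstance(self.observed, pd.Series):
            self.observed = self.observed.to_frame("total")
        if (self.observed.values <= 0).any():
            raise ValueError("observed visit counts must be positive")
        self.bounds = np.asarray(self.bounds, dtype=float)
        if np.any(self.bounds[:, 0] >= self.bounds[:, 1]):
            raise ValueError("prior bounds must be proper intervals")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        self._obs_log = {
            col: np.log(self.observed[col].to_numpy(dtype=float))
            for col in self.observed.columns
        }
        self._obs_years = self.observed.index.to_numpy(dtype=float)

    @property
    def n_params(self) -> int:
        return self.bounds.shape[0]

    def in_bounds(self, params: np.ndarray) -> bool:
        return bool(
            np.all(params >= self.bounds[:, 0]) and np.all(params <= self.bounds[:, 1]))


@dataclass
class PosteriorSample:
    """Retained Metropolis draws after burn-in."""

    draws: np.ndarray            # (n_draws, n_params)
    log_posteriors: np.ndarray
    acceptance_rate: float
    seed: int
    burn_in: int
    proposal_scales: np.ndarray
    parameter_names: tuple[str, ...] = ()

    def median(self) -> np.ndarray:
        return np.median(self.draws, axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Long format (draw, parameter, value, log_posterior)."""
        names = self.parameter_names or tuple(
            f"p{i}" for i in range(self.draws.shape[1]))
        frames = []
        for j, name in enumerate(names):
            frames.append(pd.DataFrame({
                "draw": np.arange(self.draws.shape[0]),
                "parameter": name,
                "value": self.draws[:, j],
                "log_posterior": self.log_posteriors,
            }))
        return pd.concat(frames, ignore_index=True)


class UptakeDemandSimulator:
    """Fast visit-series simulator as a function of the uptake vector.

    The population projection and prevalent pools do not depend on uptake,
    so they are precomputed once.  The care dynamics decompose by
    education stratum, and each stratum's series depends only on its own
    uptake factor; per-stratum results are cached so a component-wise
    Metropolis update re-simulates a single stratum.
    """

    def __init__(
        self,
        inputs,
        years: Sequence[int],
        dt: float = 0.25,
        population_trajectory: Sequence[dg.PopulationState] | None = None,
    ) -> None:
        self.years = np.asarray(sorted(years), dtype=int)
        self.dt = dt
        self._n_sub = round(1.0 / dt)
        if abs(self._n_sub * dt - 1.0) > 1e-9:
            raise ValueError("1/dt must be an integer")
        base_year = inputs.base_year
        if self.years[0] < base_year:
            raise ValueError("observed years precede the base year")
        horizon = int(self.years[-1])
        if population_trajectory is None:
            population_trajectory = dg.project_population(
                inputs.demographic_inputs, inputs.base_population, horizon, dt)
        self._prev = {
            int(round(s.year)): cd.collapse_ethnicity(
                pv.prevalent_all(s, inputs.prevalence_table, int(round(s.year))))
            for s in population_trajectory
        }
        self._mu = {
            y: inputs.demographic_inputs.death_rate.at(y)[ADULT_MIN_AGE:]
            for y in range(base_year, horizon + 1)
        }
        self._params = inputs.care_params
        self._base_year = base_year
        self._base_demand = inputs.base_demand_visits
        self._init_state = cd.initialize_care_state(
            self._base_demand, self._params, self._prev[base_year], base_year)
        self._cache: dict[tuple[int, float], np.ndarray] = {}

    def _run_stratum(self, edu_index: int, uptake: float) -> np.ndarray:
        """Annual visit series contributed by one education stratum."""
        key = (edu_index, float(uptake))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        params = self._params
        visit_rates = params.visit_rates()[:, None]
        comp_rates = params.completion_rates()[:, None]
        in_care = self._init_state.in_care[:, :, edu_index].copy()
        completed = self._init_state.completed[:, :, edu_index].copy()
        out = np.empty(self.years.size)
        pos = 0
        if self.years[0] == self._base_year:
            out[0] = float((in_care.sum(axis=1) * visit_rates[:, 0]).sum())
            pos = 1
        for year in range(self._base_year, int(self.years[-1])):
            decant = params.decant_at(year)[:, None]
            prev = self._prev[year][:, :, edu_index]
            mu = self._mu[year][None, :]
            for _ in range(self._n_sub):
                untreated = np.clip(prev - in_care - completed, 0.0, None)
                soc = uptake * untreated * (1.0 - decant)
                completion = comp_rates * in_care
                in_care = in_care + (soc - completion - mu * in_care) * self.dt
                completed = completed + (completion - mu * completed) * self.dt
            # whole-year boundary: age the cohorts, 100+ absorbing
            for arr in (in_care, completed):
                arr[:, -1] += arr[:, -2]
                arr[:, 1:-1] = arr[:, :-2]
                arr[:, 0] = 0.0
            if pos < self.years.size and year + 1 == self.years[pos]:
                out[pos] = float((in_care.sum(axis=1) * visit_rates[:, 0]).sum())
                pos += 1
        self._cache[key] = out
        return out

    def series_matrix(self, params: np.ndarray) -> np.ndarray:
        """Simulated visits/year, one column per education stratum."""
        return np.column_stack(
            [self._run_stratum(i, float(params[i])) for i in range(len(EDUCATIONS))])

    def series(self, params: np.ndarray) -> pd.DataFrame:
        """Simulated visits/year by education stratum at the observed years."""
        frame = pd.DataFrame(self.series_matrix(params), index=self.years,
                             columns=list(EDUCATIONS))
        frame["total"] = frame[list(EDUCATIONS)].sum(axis=1)
        return frame

    def __call__(self, params: np.ndarray) -> pd.DataFrame:
        return self.series(params)


def log_posterior(
    params: np.ndarray,
    problem: CalibrationProblem,
    model: Callable[[np.ndarray], pd.DataFrame],
) -> float:
    """Flat-prior log-posterior under log-normal observation error.

    Sums, over observed series and years, the Gaussian log-density of
    ``log(observed) - log(simulated)`` with standard deviation
    ``noise_sd``.  Out-of-bounds parameters return ``-inf``.
    """
    params = np.asarray(params, dtype=float)
    if not problem.in_bounds(params):
        return -np.inf
    sigma = problem.noise_sd
    total = 0.0

    # Fast path: a simulator exposing a plain array of per-stratum series
    # on exactly the observed years (pandas alignment is the hot-loop cost).
    matrix_fn = getattr(model, "series_matrix", None)
    sim_years = getattr(model, "years", None)
    if (matrix_fn is not None and sim_years is not None
            and np.array_equal(np.asarray(sim_years, dtype=float),
                               problem._obs_years)):
        try:
            matrix = matrix_fn(params)
        except (FloatingPointError, ValueError):
            return -np.inf
        for col, obs_log in problem._obs_log.items():
            if col == "total":
                sim_col = matrix.sum(axis=1)
            else:
                sim_col = matrix[:, EDUCATION_INDEX[col]]
            if np.any(sim_col <= 0):
                return -np.inf
            r = obs_log - np.log(sim_col)
            total += float(-0.5 * np.sum((r / sigma) ** 2)
                           - r.size * (np.log(sigma) + _LOG_SQRT_2PI))
        return total

    try:
        sim = model(params)
    except (FloatingPointError, ValueError):
        return -np.inf
    for col in problem.observed.columns:
        obs = problem.observed[col]
        sim_col = sim.loc[obs.index, col].to_numpy(dtype=float)
        if np.any(sim_col <= 0):
            return -np.inf
        r = np.log(obs.to_numpy(dtype=float)) - np.log(sim_col)
        total += float(-0.5 * np.sum((r / sigma) ** 2)
                       - obs.size * (np.log(sigma) + _LOG_SQRT_2PI))
    return total


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments."""
    n = chain.shape[0]
    a = chain[: max(int(first * n), 2)]
    b = chain[-max(int(last * n), 2):]
    va, vb = a.var(ddof=1), b.var(ddof=1)
    denom = np.sqrt(va / a.shape[0] + vb / b.shape[0])
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def _stable_burn_in(chain: np.ndarray, minimum: int) -> int:
    """Burn-in as max(minimum, shortest prefix with Geweke-stable remainder)."""
    n = chain.shape[0]
    for cut in (minimum, int(0.3 * n), int(0.4 * n), int(0.5 * n)):
        rest = chain[cut:]
        if rest.shape[0] < 10:
            break
        z = max(abs(geweke_z(rest[:, j])) for j in range(chain.shape[1]))
        if z < 2.0:
            return cut
    return minimum


def run_mcmc(
    problem: CalibrationProblem,
    model: Callable[[np.ndarray], pd.DataFrame],
    n_iterations: int = 5000,
    seed: int = 0,
    burn_in_fraction: float = 0.2,
    initial: np.ndarray | None = None,
    target_acceptance: float = 0.3,
    adapt_interval: int = 25,
) -> PosteriorSample:
    """Component-wise random-walk Metropolis, deterministic given the seed.

    Proposal scales adapt toward the target acceptance rate during the
    burn-in phase only; the burn-in actually discarded is the larger of
    the configured fraction and a Geweke-stable prefix.  Raises if the
    chain accepts nothing after adaptation.
    """
    if n_iterations < 10:
        raise ValueError("n_iterations too small")
    rng = np.random.default_rng(seed)
    n_params = problem.n_params
    widths = problem.bounds[:, 1] - problem.bounds[:, 0]
    scales = 0.1 * widths
    if initial is None:
        current = problem.bounds[:, 0] + 0.5 * widths
    else:
        current = np.asarray(initial, dtype=float).copy()
    current_lp = log_posterior(current, problem, model)
    if not np.isfinite(current_lp):
        raise ValueError("initial point has zero posterior density")

    burn = int(burn_in_fraction * n_iterations)
    chain = np.empty((n_iterations, n_params))
    lps = np.empty(n_iterations)
    accepts = np.zeros(n_params)
    window_accepts = np.zeros(n_params)
    post_burn_accepts = 0
    post_burn_proposals = 0

    for it in range(n_iterations):
        for j in range(n_params):
            proposal = current.copy()
            proposal[j] += rng.normal(0.0, scales[j])
            lp = log_posterior(proposal, problem, model)
            if np.log(rng.uniform()) < lp - current_lp:
                current, current_lp = proposal, lp
                accepts[j] += 1
                window_accepts[j] += 1
                if it >= burn:
                    post_burn_accepts += 1
            if it >= burn:
                post_burn_proposals += 1
        chain[it] = current
        lps[it] = current_lp
        if it < burn and (it + 1) % adapt_interval == 0:
            rate = window_accepts / adapt_interval
            scales *= np.where(rate > target_acceptance, 1.25, 0.8)
            np.clip(scales, 1e-6 * widths, widths, out=scales)
            window_accepts[:] = 0.0

    cut = _stable_burn_in(chain, burn)
    acceptance = post_burn_accepts / max(post_burn_proposals, 1)
    if acceptance == 0.0:
        raise RuntimeError("Metropolis chain accepted no proposals after burn-in")
    return PosteriorSample(
        draws=chain[cut:],
        log_posteriors=lps[cut:],
        acceptance_rate=float(acceptance),
        seed=seed,
        burn_in=cut,
        proposal_scales=scales,
        parameter_names=problem.parameter_names,
    )


def propagate_uncertainty(
    sample: PosteriorSample,
    runner: Callable[[np.ndarray], Mapping[str, pd.Series]],
    level: float = 0.95,
    max_runs: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Credible intervals of model outputs across posterior draws.

    ``runner`` maps a parameter vector to named annual output series
    (e.g. demand, required ophthalmologists).  Draws may be thinned to
    ``max_runs`` evenly spaced re-runs.  Returns, per output, a DataFrame
    indexed by year with ``lo``/``hi`` percentile columns
    (linear-interpolation percentiles at (1-level)/2 and 1-(1-level)/2).
    """
    draws = sample.draws
    if draws.shape[0] == 0:
        raise ValueError("posterior sample is empty")
    if max_runs is not None and draws.shape[0] > max_runs:
        idx = np.linspace(0, draws.shape[0] - 1, max_runs).round().astype(int)
        draws = draws[idx]
    outputs: dict[str, list[pd.Series]] = {}
    for params in draws:
        result = runner(params)
        for name, series in result.items():
            outputs.setdefault(name, []).append(series)
    alpha = 100.0 * (1.0 - level) / 2.0
    intervals = {}
    for name, series_list in outputs.items():
        table = pd.concat(series_list, axis=1).to_numpy(dtype=float)
        lo = np.percentile(table, alpha, axis=1)
        hi = np.percentile(table, 100.0 - alpha, axis=1)
        intervals[name] = pd.DataFrame(
            {"lo": lo, "hi": hi}, index=series_list[0].index)
    return intervals
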