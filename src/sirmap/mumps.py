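"""Mumps-in-China application scenario.

Mumps confers permanent immunity, so the SIR structure applies.  The host
population is the Chinese population younger than 20, the time step is one
day, and the scenario constants are derived from published demographic and
notifiable-disease figures for 2005:

* recruitment Λ = 44,054 individuals/day (births into the under-20 class);
* natural exit μ = 0.00015634/day, the sum of the daily death rate
  (annual 7.06/1000 → 19.34 per million per day) and the daily ageing-out
  rate (1/7300, a 20-year horizon in days);
* recovery γ = 1/12 ≈ 0.0833/day (a 10–14 day course of illness);
* disease-induced mortality δ = 3e-7/day;
* transmission β = 0.08518/day, giving R0 ≈ 1.02;
* initial state S = 353,117,392, I = 8,508, R = 6,000,000 on 2005-01-01.

The scenario simulates 2005–2015, aggregates per-step incidence into
annual new-case counts, and fits β to an annual case series by bounded
least squares.  The reported Chinese case counts themselves are not
shipped; :func:`synthesize_incidence` generates synthetic annual series
(optionally with Poisson reporting noise) from a known-β forward run, and
the fit is validated by parameter recovery on those.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar

from .model import EpidemicState, ModelParameters, Trajectory, simulate

logger = logging.getLogger("sirmap")

STEPS_PER_YEAR = 365
START_YEAR = 2005


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + sig - 1)


@dataclass(frozen=True)
class MortalityRates:
    """Daily natural-exit rate μ assembled from printed demographic inputs."""

    death_daily: float  # annual per-1000 rate / 365, 4 significant figures
    exit_daily: float  # 1 / exit horizon in days, 3 significant figures
    total: float  # sum of the rounded components (the printed μ)
    total_unrounded: float


def derive_death_and_exit_rate(
    annual_death_per_1000: float, exit_horizon_days: int
) -> MortalityRates:
    """Daily μ = daily death rate + daily ageing-out rate.

    Components are rounded the way the printed figures are (death rate to
    4 significant figures, exit rate to 3) so the published μ is
    reproduced exactly; the unrounded sum is exposed alongside.
    """
    if annual_death_per_1000 < 0 or exit_horizon_days <= 0:
        raise ValueError("rates must be positive")
    death_exact = annual_death_per_1000 / 1000.0 / 365.0
    exit_exact = 1.0 / exit_horizon_days
    death = _round_sig(death_exact, 4)
    exit_ = _round_sig(exit_exact, 3)
    return MortalityRates(death, exit_, death + exit_, death_exact + exit_exact)


@dataclass(frozen=True)
class ScenarioConfig:
    """A dated forward-simulation setup (parameters, start state, horizon)."""

    params: ModelParameters
    state0: EpidemicState
    start_label: str = "2005-01-01"
    years: int = 11
    steps_per_year: int = STEPS_PER_YEAR

    @property
    def horizon(self) -> int:
        return self.years * self.steps_per_year

    @property
    def start_year(self) -> int:
        return int(self.start_label[:4])


def mumps_config(years: int = 11) -> ScenarioConfig:
    """The frozen mumps scenario constants (2005 start, daily step)."""
    mu = derive_death_and_exit_rate(7.06, 7300).total  # 0.00015634
    params = ModelParameters(
        Lambda=44_054.0,
        beta=0.08518,
        mu=mu,
        delta=0.0000003,
        gamma=0.0833,  # 1/12 to the printed precision
    )
    state0 = EpidemicState(353_117_392.0, 8_508.0, 6_000_000.0)
    return ScenarioConfig(params, state0, "2005-01-01", years)


@dataclass(frozen=True)
class AnnualIncidence:
    """New-case counts aggregated over consecutive whole years."""

    years: tuple[int, ...]
    cases: np.ndarray

    def __len__(self) -> int:
        return len(self.years)


def run_scenario(config: ScenarioConfig, *, t0: int = 1) -> Trajectory:
    """Forward-simulate the scenario (time labels start at t0 = 1 by the
    application's convention)."""
    return simulate(config.state0, config.params, config.horizon, t0=t0)


def annual_cases(
    trajectory: Trajectory,
    steps_per_year: int = STEPS_PER_YEAR,
    start_year: int = START_YEAR,
) -> AnnualIncidence:
    """Sum per-step incidence into consecutive blocks of one year.

    A partial trailing year is dropped (and logged).
    """
    inc = trajectory.incidence
    if len(inc) < steps_per_year:
        raise ValueError("trajectory shorter than one year")
    n_years = len(inc) // steps_per_year
    dropped = len(inc) - n_years * steps_per_year
    if dropped:
        logger.info("annual_cases: dropping %d trailing sub-year steps", dropped)
    blocks = inc[: n_years * steps_per_year].reshape(n_years, steps_per_year)
    return AnnualIncidence(
        tuple(range(start_year, start_year + n_years)), blocks.sum(axis=1)
    )


def synthesize_incidence(
    config: ScenarioConfig,
    noise: str | None = None,
    seed: int | None = None,
) -> AnnualIncidence:
    """Annual case counts from a forward run, optionally Poisson-noised.

    ``noise=None`` returns the deterministic aggregation;
    ``noise="poisson"`` draws each year independently with mean equal to
    the simulated count (reporting noise for count data).
    """
    ann = annual_cases(run_scenario(config), config.steps_per_year,
                       config.start_year)
    if noise is None:
        return ann
    if noise != "poisson":
        raise ValueError(f"unknown noise model {noise!r}")
    rng = np.random.default_rng(seed)
    return AnnualIncidence(ann.years, rng.poisson(ann.cases).astype(float))


@dataclass(frozen=True)
class FitResult:
    beta: float
    sse: float
    at_lower_bound: bool
    at_upper_bound: bool

    @property
    def flagged(self) -> bool:
        return self.at_lower_bound or self.at_upper_bound


def fit_beta(
    observed: AnnualIncidence,
    template: ScenarioConfig,
    beta_bounds: tuple[float, float] = (0.02, 0.2),
    *,
    xatol: float = 1e-7,
    log_scale: bool = False,
    grid_points: int = 25,
) -> FitResult:
    """Least-squares fit of β to an annual case series.

    Minimizes the sum of squared differences between simulated and
    observed annual counts over β in ``beta_bounds`` (counts are large
    and roughly homoscedastic at this scale, so plain squared error is
    the default — ``log_scale`` switches to squared error on log1p
    counts).  The objective can develop secondary minima when the
    epidemic peak slides across year boundaries, so a coarse grid
    pre-search brackets the global minimum before a bounded scalar
    minimization refines it to ``xatol`` in β.  A minimizer within
    tolerance of a bound is flagged, not raised.
    """
    lo, hi = beta_bounds
    if not lo < hi:
        raise ValueError("beta bounds must satisfy lo < hi")
    obs = np.asarray(observed.cases, dtype=float)
    n_years = len(obs)
    cfg = replace(template, years=n_years)

    def objective(beta: float) -> float:
        sim = annual_cases(
            run_scenario(replace(cfg, params=replace(cfg.params, beta=beta))),
            cfg.steps_per_year,
            cfg.start_year,
        ).cases
        if log_scale:
            return float(np.sum((np.log1p(sim) - np.log1p(obs)) ** 2))
        return float(np.sum((sim - obs) ** 2))

    grid = np.linspace(lo, hi, max(grid_points, 3))
    values = [objective(b) for b in grid]
    best = int(np.argmin(values))
    b_lo = grid[max(best - 1, 0)]
    b_hi = grid[min(best + 1, len(grid) - 1)]
    res = minimize_scalar(
        objective, bounds=(b_lo, b_hi), method="bounded",
        options={"xatol": xatol},
    )
    beta = float(res.x)
    if values[best] < res.fun:  # refinement must never lose to the grid
        beta, res_fun = float(grid[best]), values[best]
    else:
        res_fun = float(res.fun)
    span = hi - lo
    at_lo = beta - lo < 1e-3 * span
    at_hi = hi - beta < 1e-3 * span
    if at_lo or at_hi:
        logger.warning("fit_beta: minimizer at the %s bound (beta=%g)",
                       "lower" if at_lo else "upper", beta)
    return FitResult(beta, res_fun, at_lo, at_hi)
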