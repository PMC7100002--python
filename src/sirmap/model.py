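"""Discrete-time SIR epidemic map.

The model advances susceptible (S), infective (I) and recovered (R)
compartment sizes in discrete time steps::

    S(t+1) = S(t) + Λ − β S(t) I(t) / N(t) − μ S(t)
    I(t+1) = I(t) + β S(t) I(t) / N(t) − (μ + δ + γ) I(t)
    R(t+1) = R(t) + γ I(t) − μ R(t)

with N = S + I + R, constant recruitment Λ, standard-incidence transmission
rate β, natural mortality μ, disease-induced mortality δ and recovery rate γ
(all per time step).  New infections per step (the incidence) are
β S I / N.  The basic reproduction number is R0 = β / (μ + δ + γ).

Compartments are continuous non-negative reals.  Solutions started in the
invariant domain Ω1 = {S + I + R ≤ Λ/μ, components ≥ 0} stay non-negative
whenever the feasibility conditions β + μ < 1 and μ + δ + γ < 1 hold.
Outside that parameter regime the raw map can push a compartment below
zero; :func:`simulate` then either clips at zero (counting every clipping
event) or, on request, iterates the raw map unchanged — the latter is what
the bifurcation analysis in :mod:`sirmap.dynamics` uses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("sirmap")

#: relative tolerance meant by "equal" for floating-point model quantities
REL_TOL = 1e-9


class SimulationError(RuntimeError):
    """A trajectory became non-finite; carries the offending step index."""

    def __init__(self, message: str, step_index: int):
        super().__init__(message)
        self.step_index = step_index


@dataclass(frozen=True)
class ModelParameters:
    """The five per-step rates of the map.

    Parameters
    ----------
    Lambda : recruitment into the susceptible class (individuals / step).
    beta : transmission rate (per step).
    mu : natural death rate (per step).
    delta : disease-induced death rate (per step).
    gamma : recovery rate (per step).
    """

    Lambda: float
    beta: float
    mu: float
    delta: float
    gamma: float

    def __post_init__(self):
        for name in ("Lambda", "beta", "mu", "delta", "gamma"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v!r}")

    @property
    def exit_rate(self) -> float:
        """Total per-step exit rate from the infective class, μ + δ + γ."""
        return self.mu + self.delta + self.gamma

    @property
    def feasible(self) -> bool:
        """Whether β + μ < 1 and μ + δ + γ < 1 (non-negativity conditions)."""
        return self.beta + self.mu < 1.0 and self.exit_rate < 1.0

    @property
    def carrying_capacity(self) -> float:
        """Ceiling Λ/μ of the invariant domain Ω1."""
        if self.mu <= 0:
            raise ValueError("carrying capacity Λ/μ requires mu > 0")
        return self.Lambda / self.mu

    def with_r0(self, r0: float) -> "ModelParameters":
        """Return a copy with β chosen so that R0 equals ``r0``."""
        return replace(self, beta=r0 * self.exit_rate)


@dataclass(frozen=True)
class EpidemicState:
    """Compartment sizes at one time step (N = S + I + R is derived).

    Compartments are ordinarily non-negative; operations that require
    non-negativity check it explicitly, so intermediate states of the raw
    map in the infeasible parameter regime may carry negative components.
    """

    S: float
    I: float
    R: float

    def __post_init__(self):
        for name in ("S", "I", "R"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def N(self) -> float:
        return self.S + self.I + self.R

    @property
    def nonnegative(self) -> bool:
        return self.S >= 0 and self.I >= 0 and self.R >= 0

    def in_invariant_domain(self, params: ModelParameters) -> bool:
        """Membership in Ω1: components ≥ 0 and N ≤ Λ/μ (inclusive)."""
        return self.nonnegative and self.N <= params.carrying_capacity

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.S, self.I, self.R)


@dataclass(frozen=True)
class FeasibilityReport:
    """Booleans for the parameter and initial-condition requirements."""

    condition_4a: bool  # β + μ < 1
    condition_4b: bool  # μ + δ + γ < 1
    initial_in_domain: bool  # components ≥ 0 and S0+I0+R0 ≤ Λ/μ
    messages: tuple[str, ...] = ()

    @property
    def all_ok(self) -> bool:
        return self.condition_4a and self.condition_4b and self.initial_in_domain


@dataclass
class Trajectory:
    """Iterates of the map: times, states and per-step incidence.

    ``states`` has shape (horizon+1, 3) in (S, I, R) order; ``incidence``
    has length horizon, entry t holding β S(t) I(t) / N(t).
    """

    times: np.ndarray
    states: np.ndarray
    incidence: np.ndarray
    params: ModelParameters
    clip_events: int = 0
    feasible: bool = True
    warnings: list[str] = field(default_factory=list)

    @property
    def S(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def I(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def R(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def N(self) -> np.ndarray:
        return self.states.sum(axis=1)

    @property
    def horizon(self) -> int:
        return len(self.times) - 1

    def final_state(self) -> EpidemicState:
        return EpidemicState(*self.states[-1])

    def to_frame(self) -> pd.DataFrame:
        inc = np.concatenate([self.incidence, [np.nan]])
        return pd.DataFrame(
            {
                "t": self.times,
                "S": self.S,
                "I": self.I,
                "R": self.R,
                "N": self.N,
                "incidence": inc,
            }
        )


def _force_of_infection(beta: float, S: float, I: float, N: float) -> float:
    # βSI/N extended continuously by 0 at N = 0 (S = I = 0 there).
    if N == 0.0:
        return 0.0
    return beta * S * I / N


def step(state: EpidemicState, params: ModelParameters) -> EpidemicState:
    """One exact application of the map.

    The input state must be non-negative and finite.  The returned state is
    the exact image, which is guaranteed non-negative only under the
    feasibility conditions; no clipping is applied here.
    """
    if not state.nonnegative:
        raise ValueError(f"step requires non-negative state, got {state}")
    S, I, R = state.S, state.I, state.R
    inf = _force_of_infection(params.beta, S, I, S + I + R)
    return EpidemicState(
        S + params.Lambda - inf - params.mu * S,
        I + inf - params.exit_rate * I,
        R + params.gamma * I - params.mu * R,
    )


def simulate(
    state0: EpidemicState,
    params: ModelParameters,
    horizon: int,
    *,
    clip: bool = True,
    t0: int = 0,
) -> Trajectory:
    """Iterate the map ``horizon`` times, recording states and incidence.

    Parameters
    ----------
    clip : if True (default), any component that the raw map pushes below
        zero is set to zero and the event counted in ``clip_events``.  With
        ``clip=False`` the raw map is iterated unchanged (needed to study
        the period-doubling regime, where clipping alters the attractor).
    t0 : label of the first time point (output labelling only).
    """
    if not isinstance(horizon, (int, np.integer)) or horizon < 1:
        raise ValueError(f"horizon must be a positive integer, got {horizon!r}")
    if not state0.nonnegative:
        raise ValueError(f"initial state must be non-negative, got {state0}")

    p = params
    warnings: list[str] = []
    if not p.feasible:
        warnings.append(
            "parameters violate the feasibility conditions "
            f"(beta+mu={p.beta + p.mu:g}, mu+delta+gamma={p.exit_rate:g}); "
            "non-negativity of the solution is not guaranteed"
        )
        logger.warning(warnings[-1])

    states = np.empty((horizon + 1, 3))
    inc = np.empty(horizon)
    S, I, R = state0.S, state0.I, state0.R
    states[0] = (S, I, R)
    clip_events = 0
    Lam, beta, mu, gamma = p.Lambda, p.beta, p.mu, p.gamma
    exit_rate = p.exit_rate
    for t in range(horizon):
        N = S + I + R
        foi = beta * S * I / N if N != 0.0 else 0.0
        inc[t] = foi
        S, I, R = (
            S + Lam - foi - mu * S,
            I + foi - exit_rate * I,
            R + gamma * I - mu * R,
        )
        if clip:
            if S < 0 or I < 0 or R < 0:
                clip_events += 1
                S, I, R = max(S, 0.0), max(I, 0.0), max(R, 0.0)
        if not (math.isfinite(S) and math.isfinite(I) and math.isfinite(R)):
            raise SimulationError(
                f"trajectory became non-finite at step {t + 1}", t + 1
            )
        states[t + 1] = (S, I, R)
    if clip_events:
        warnings.append(f"{clip_events} clipping event(s) during the run")
        logger.warning(warnings[-1])
    return Trajectory(
        times=t0 + np.arange(horizon + 1),
        states=states,
        incidence=inc,
        params=p,
        clip_events=clip_events,
        feasible=p.feasible,
        warnings=warnings,
    )


def basic_reproduction_number(params: ModelParameters) -> float:
    """R0 = β / (μ + δ + γ)."""
    if params.exit_rate <= 0:
        raise ValueError("R0 undefined: mu + delta + gamma must be positive")
    return params.beta / params.exit_rate


def check_feasibility(
    params: ModelParameters, state0: EpidemicState
) -> FeasibilityReport:
    """Evaluate the non-negativity conditions and initial-domain membership.

    This is a reporting operation: infeasible values are described, never
    raised on.
    """
    cond_a = params.beta + params.mu < 1.0
    cond_b = params.exit_rate < 1.0
    if params.mu > 0:
        in_domain = state0.in_invariant_domain(params)
    else:
        in_domain = state0.nonnegative
    msgs = []
    if not cond_a:
        msgs.append(f"beta + mu = {params.beta + params.mu:g} >= 1")
    if not cond_b:
        msgs.append(f"mu + delta + gamma = {params.exit_rate:g} >= 1")
    if not in_domain:
        msgs.append("initial state outside the invariant domain Omega_1")
    return FeasibilityReport(cond_a, cond_b, in_domain, tuple(msgs))


def total_population_closed_form(N0, params: ModelParameters, t):
    """Closed-form N(t) = Λ(1−(1−μ)^t)/μ + (1−μ)^t N0, valid when δ = 0.

    With no disease-induced mortality the total population decouples from
    the epidemic and follows a linear recursion whose solution this is;
    it tends to Λ/μ as t → ∞.  Accepts scalar or array ``t``.
    """
    if params.delta != 0:
        raise ValueError("closed form for N(t) requires delta = 0 exactly")
    mu = params.mu
    if not 0 < mu < 1:
        raise ValueError("closed form for N(t) requires mu in (0, 1)")
    decay = np.power(1.0 - mu, t)
    return params.Lambda * (1.0 - decay) / mu + decay * N0
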