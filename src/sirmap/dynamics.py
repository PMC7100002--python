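"""Attractor-period detection, bifurcation scans and transition location.

With the per-step rates fixed at small values and β (equivalently R0) swept
upward past the feasibility bound β + μ < 1, the endemic equilibrium of the
SIR map loses stability through a flip (period-doubling) bifurcation and a
cascade 1 → 2 → 4 → 8 → … → chaos follows.  Two independent instruments
locate transitions:

* :func:`locate_stability_loss` bisects on the spectral radius of the
  endemic-equilibrium Jacobian crossing 1 — initial-condition free and the
  sharper of the two for the first transition;
* :func:`locate_period_doubling` bisects on the attractor period detected
  from long post-transient orbits, and works for every doubling.

All orbits here iterate the raw map (``clip=False``): clipping negative
excursions to zero alters the attractor in the β > 1 regime and suppresses
the cascade, so it would not reproduce the period-doubling route observed
in the unconstrained map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import (
    EpidemicState,
    ModelParameters,
    SimulationError,
    Trajectory,
    basic_reproduction_number,
)
from .equilibria import endemic_jacobian

#: default post-transient observation window (steps)
DEFAULT_WINDOW = 512
#: default transient length; eigenvalues near criticality are close to 1,
#: so convergence onto the attractor is slow
DEFAULT_TRANSIENT = 50_000
DEFAULT_TOL = 1e-6
ABS_FLOOR = 1e-9
DEFAULT_MAX_PERIOD = 64


@dataclass(frozen=True)
class AttractorSummary:
    """Detected attractor at one parameter value.

    ``period`` is the smallest recurrence period found within
    ``max_period``; None means no period was detected (aperiodic/chaotic
    at the inspected resolution).  ``transitional`` flags points where the
    two halves of the observation window disagree — typical in a narrow
    band around a doubling.
    """

    beta: float
    r0: float
    period: int | None
    samples: np.ndarray  # post-transient I values
    clip_events: int = 0
    transitional: bool = False


@dataclass
class BifurcationScan:
    beta_grid: np.ndarray
    r0_grid: np.ndarray
    summaries: list[AttractorSummary | None]
    params: ModelParameters  # fixed rates; beta taken from the grid
    transient: int
    window: int
    errors: list[tuple[int, str]]


def default_scan_state(params: ModelParameters) -> EpidemicState:
    """Deterministic start inside Ω1: (S, I, R) = (0.9, 0.1, 0)·Λ/μ."""
    cap = params.carrying_capacity
    return EpidemicState(0.9 * cap, 0.1 * cap, 0.0)


def _iterate(params: ModelParameters, state: tuple[float, float, float],
             nsteps: int, record: int = 0, clip: bool = False):
    """Fast scalar loop: advance ``nsteps``, recording the last ``record``
    I values.  Returns (final (S,I,R), I-buffer, clip events)."""
    S, I, R = state
    Lam, beta, mu, gamma = params.Lambda, params.beta, params.mu, params.gamma
    exit_rate = params.exit_rate
    buf = np.empty(record) if record else None
    first_rec = nsteps - record
    nclip = 0
    for t in range(nsteps):
        N = S + I + R
        foi = beta * S * I / N if N != 0.0 else 0.0
        S, I, R = (
            S + Lam - foi - mu * S,
            I + foi - exit_rate * I,
            R + gamma * I - mu * R,
        )
        if clip and (S < 0.0 or I < 0.0 or R < 0.0):
            nclip += 1
            S, I, R = max(S, 0.0), max(I, 0.0), max(R, 0.0)
        if not (math.isfinite(S) and math.isfinite(I) and math.isfinite(R)):
            raise SimulationError(f"orbit diverged at step {t + 1}", t + 1)
        if t >= first_rec:
            buf[t - first_rec] = I
    return (S, I, R), buf, nclip


def _smallest_period(buf: np.ndarray, tol: float, max_period: int) -> int | None:
    scale = max(float(np.max(np.abs(buf))), ABS_FLOOR)
    thresh = tol * scale + ABS_FLOOR
    for p in range(1, max_period + 1):
        if np.all(np.abs(buf[p:] - buf[:-p]) < thresh):
            return p
    return None


def detect_attractor_period(
    params: ModelParameters,
    state0: EpidemicState | None = None,
    *,
    transient: int = DEFAULT_TRANSIENT,
    window: int = DEFAULT_WINDOW,
    tol: float = DEFAULT_TOL,
    max_period: int = DEFAULT_MAX_PERIOD,
    clip: bool = False,
) -> AttractorSummary:
    """Iterate past the transient, then detect the attractor period.

    The period is the smallest p ≤ ``max_period`` such that the
    post-transient I sequence satisfies |I(t+p) − I(t)| < tol·scale with an
    absolute floor.  If the two halves of the window disagree the summary
    is flagged ``transitional`` and carries the larger period (None, i.e.
    undetected, counts as larger than any integer).
    """
    if transient < 1:
        raise ValueError("transient must be >= 1")
    if window < 2 * max_period:
        raise ValueError("window must be at least 2 * max_period")
    if state0 is None:
        state0 = default_scan_state(params)
    _, buf, nclip = _iterate(
        params, state0.as_tuple(), transient + window, record=window, clip=clip
    )
    period = _smallest_period(buf, tol, max_period)
    half = window // 2
    p1 = _smallest_period(buf[:half], tol, max_period)
    p2 = _smallest_period(buf[half:], tol, max_period)
    transitional = p1 != p2
    if transitional:
        candidates = [p for p in (p1, p2) if p is not None]
        period = max(candidates) if len(candidates) == 2 else None
    return AttractorSummary(
        beta=params.beta,
        r0=basic_reproduction_number(params),
        period=period,
        samples=buf,
        clip_events=nclip,
        transitional=transitional,
    )


def bifurcation_scan(
    params: ModelParameters,
    beta_grid,
    state0: EpidemicState | None = None,
    *,
    transient: int = DEFAULT_TRANSIENT,
    window: int = DEFAULT_WINDOW,
    tol: float = DEFAULT_TOL,
    max_period: int = DEFAULT_MAX_PERIOD,
    clip: bool = False,
) -> BifurcationScan:
    """One attractor summary per β grid point (grid strictly increasing).

    Points are independent of each other; a per-point failure is recorded
    in ``errors`` and the scan continues.
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    if beta_grid.size == 0:
        raise ValueError("beta grid must be non-empty")
    if beta_grid.size > 1 and not np.all(np.diff(beta_grid) > 0):
        raise ValueError("beta grid must be strictly increasing")
    summaries: list[AttractorSummary | None] = []
    errors: list[tuple[int, str]] = []
    for i, b in enumerate(beta_grid):
        p = ModelParameters(params.Lambda, float(b), params.mu, params.delta,
                            params.gamma)
        try:
            summaries.append(
                detect_attractor_period(
                    p, state0, transient=transient, window=window, tol=tol,
                    max_period=max_period, clip=clip,
                )
            )
        except Exception as exc:  # per-point failure must not kill the scan
            summaries.append(None)
            errors.append((i, str(exc)))
    r0_grid = beta_grid / params.exit_rate
    return BifurcationScan(
        beta_grid, r0_grid, summaries, params, transient, window, errors
    )


def locate_stability_loss(
    params: ModelParameters, r0_lo: float, r0_hi: float, tol: float = 1e-3
) -> float:
    """Critical R0 where the endemic equilibrium loses local stability.

    Bisects (Brent) on the spectral radius of the endemic-equilibrium
    Jacobian crossing 1, with β = R0·(μ+δ+γ).  The bracket must straddle
    the transition: radius < 1 at ``r0_lo`` and > 1 at ``r0_hi``.
    """

    def margin(r0: float) -> float:
        return endemic_jacobian(params.with_r0(r0)).spectral_radius - 1.0

    lo, hi = margin(r0_lo), margin(r0_hi)
    if not (lo < 0 < hi):
        raise ValueError(
            "bracket does not straddle the stability loss: "
            f"radius-1 is {lo:.3g} at R0={r0_lo} and {hi:.3g} at R0={r0_hi}"
        )
    return float(brentq(margin, r0_lo, r0_hi, xtol=tol))


def locate_period_doubling(
    params: ModelParameters,
    r0_lo: float,
    r0_hi: float,
    from_period: int = 1,
    tol: float = 0.05,
    *,
    transient: int = DEFAULT_TRANSIENT,
    window: int = DEFAULT_WINDOW,
    detect_tol: float = DEFAULT_TOL,
    max_period: int = DEFAULT_MAX_PERIOD,
    state0: EpidemicState | None = None,
) -> float:
    """Transition R0 where the attractor period doubles from ``from_period``.

    Bisection on the detected period: a point whose period is ≤
    ``from_period`` (and not transitional) is on the low side, anything
    else — higher period, transitional, or undetected — on the high side.
    For ``from_period=1`` the result agrees with
    :func:`locate_stability_loss` to within the bisection tolerance.
    """

    def detect(r0: float) -> AttractorSummary:
        return detect_attractor_period(
            params.with_r0(r0), state0, transient=transient, window=window,
            tol=detect_tol, max_period=max_period,
        )

    def low_side(s: AttractorSummary) -> bool:
        return (not s.transitional) and s.period is not None \
            and s.period <= from_period

    s_lo, s_hi = detect(r0_lo), detect(r0_hi)
    if not low_side(s_lo):
        raise ValueError(
            f"invalid bracket: period at R0={r0_lo} is {s_lo.period} "
            f"(expected <= {from_period})"
        )
    if low_side(s_hi):
        raise ValueError(
            f"invalid bracket: period at R0={r0_hi} is {s_hi.period} "
            f"(expected > {from_period})"
        )
    lo, hi = r0_lo, r0_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if low_side(detect(mid)):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def empirical_persistence_floor(trajectory: Trajectory, burn_in: int) -> float:
    """min I(t) over t > burn_in — an empirical lower bound witnessing
    persistence (positive when R0 > 1 and I(0) > 0)."""
    if burn_in >= trajectory.horizon:
        raise ValueError("burn_in must be shorter than the trajectory")
    return float(np.min(trajectory.I[burn_in + 1 :]))
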