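"""Equilibria of the SIR map and their local stability.

The map has the disease-free equilibrium E0 = (Λ/μ, 0, 0) and, when
R0 = β/(μ+δ+γ) > 1, a unique endemic equilibrium

    S* = Λ(μ+γ) / (μ D),   I* = Λ(R0−1) / D,   R* = γ I* / μ,
    D  = (μ+δ+γ)(R0−1) + (μ+γ),

with total N* = Λ(μ+γ)R0 / (μ D).

Local stability is read from the linearization.  At E0 the eigenvalues are
{1−μ, 1−μ, 1+β−μ−δ−γ}.  At the endemic equilibrium the natural coordinates
are (N, I, R): the linearization A1 there has characteristic polynomial
(1−μ−λ)·φ1(λ) with the quadratic factor

    φ1(λ) = λ² − (2−μ−q) λ + (1−μ)(1−q) + γ q + δ p,
    q = β I*/N*,   p = β I*(I*+R*)/N*²,

so one eigenvalue is exactly 1−μ and the other two are the roots of φ1.
The Jury criterion decides whether both roots of a real quadratic
λ² + bλ + c lie strictly inside the unit circle:  φ(1) = 1+b+c > 0,
φ(−1) = 1−b+c > 0 and |c| < 1.

Eigenvalues are computed from the factored form; a generic eigensolver on
the full matrix serves as an independent oracle in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ModelParameters, EpidemicState, basic_reproduction_number

#: half-width of the band around |λ|=1 classified as "marginal"
MARGINAL_TOL = 1e-9


@dataclass(frozen=True)
class EquilibriumPoint:
    """A fixed point of the map, disease-free or endemic."""

    kind: str  # "disease_free" | "endemic"
    S: float
    I: float
    R: float

    @property
    def N(self) -> float:
        return self.S + self.I + self.R

    def as_state(self) -> EpidemicState:
        return EpidemicState(self.S, self.I, self.R)


@dataclass(frozen=True)
class JuryTest:
    """The three Jury quantities for λ² + bλ + c and the resulting verdict.

    ``boundary`` flags a test quantity sitting on its boundary (within
    tolerance): φ(±1) = 0 or |c| = 1, i.e. a root on the unit circle.
    """

    phi_at_1: float
    phi_at_minus1: float
    constant: float
    verdict: str  # "stable" | "unstable" | "marginal"
    boundary: bool = False

    @property
    def stable(self) -> bool:
        return self.verdict == "stable"


@dataclass(frozen=True)
class StabilityReport:
    """Linearization at an equilibrium and the stability verdict."""

    equilibrium: EquilibriumPoint
    jacobian: np.ndarray
    eigenvalues: np.ndarray  # complex, length 3
    spectral_radius: float
    verdict: str  # "stable" | "unstable" | "marginal"
    jury: JuryTest | None = None
    coordinates: str = "SIR"  # coordinate system of `jacobian`


def _verdict_from_radius(rho: float, tol: float = MARGINAL_TOL) -> str:
    if abs(rho - 1.0) < tol:
        return "marginal"
    return "stable" if rho < 1.0 else "unstable"


def disease_free_equilibrium(params: ModelParameters) -> EquilibriumPoint:
    """E0 = (Λ/μ, 0, 0)."""
    if params.mu <= 0:
        raise ValueError("disease-free equilibrium requires mu > 0")
    return EquilibriumPoint("disease_free", params.Lambda / params.mu, 0.0, 0.0)


def endemic_equilibrium(params: ModelParameters) -> EquilibriumPoint | None:
    """The unique positive fixed point, or None when R0 ≤ 1."""
    if params.mu <= 0:
        raise ValueError("endemic equilibrium requires mu > 0")
    r0 = basic_reproduction_number(params)
    if r0 <= 1.0:
        return None
    mu, gamma = params.mu, params.gamma
    D = params.exit_rate * (r0 - 1.0) + (mu + gamma)
    S = params.Lambda * (mu + gamma) / (mu * D)
    I = params.Lambda * (r0 - 1.0) / D
    R = gamma * I / mu
    return EquilibriumPoint("endemic", S, I, R)


def endemic_total_population(params: ModelParameters) -> float:
    """N* = Λ(μ+γ)R0 / (μ D); equals Λ/μ exactly when δ = 0."""
    eq = endemic_equilibrium(params)
    if eq is None:
        raise ValueError("no endemic equilibrium: R0 <= 1")
    r0 = basic_reproduction_number(params)
    mu, gamma = params.mu, params.gamma
    D = params.exit_rate * (r0 - 1.0) + (mu + gamma)
    return params.Lambda * (mu + gamma) * r0 / (mu * D)


def sir_jacobian(params: ModelParameters, state: EpidemicState) -> np.ndarray:
    """Analytic Jacobian of the (S, I, R) map at an arbitrary state.

    Exposed for cross-checks: at the endemic equilibrium its spectrum must
    coincide with that of the (N, I, R) linearization (the coordinate
    change is linear and invertible).
    """
    S, I, R = state.S, state.I, state.R
    N = S + I + R
    if N == 0:
        dSI = np.zeros((2, 3))
    else:
        b = params.beta
        # d(SI/N)/d(S,I,R)
        g_S = I * (I + R) / N**2
        g_I = S * (S + R) / N**2
        g_R = -S * I / N**2
        dSI = b * np.array([[g_S, g_I, g_R], [g_S, g_I, g_R]])
    mu, gamma = params.mu, params.gamma
    J = np.array(
        [
            [1.0 - mu, 0.0, 0.0],
            [0.0, 1.0 - params.exit_rate, 0.0],
            [0.0, gamma, 1.0 - mu],
        ]
    )
    J[0] -= dSI[0]
    J[1] += dSI[1]
    return J


def dfe_jacobian(params: ModelParameters) -> StabilityReport:
    """Linearization at E0 with exact eigenvalues {1−μ, 1−μ, 1+β−μ−δ−γ}.

    Under the feasibility conditions the verdict is "stable" iff R0 < 1.
    """
    eq = disease_free_equilibrium(params)
    mu, beta, gamma = params.mu, params.beta, params.gamma
    lam3 = 1.0 + beta - params.exit_rate
    A = np.array(
        [
            [1.0 - mu, -beta, 0.0],
            [0.0, lam3, 0.0],
            [0.0, gamma, 1.0 - mu],
        ]
    )
    eig = np.array([1.0 - mu, 1.0 - mu, lam3], dtype=complex)
    rho = float(np.max(np.abs(eig)))
    return StabilityReport(eq, A, eig, rho, _verdict_from_radius(rho))


def jury_quadratic_test(b: float, c: float, *, tol: float = MARGINAL_TOL) -> JuryTest:
    """Jury criterion for λ² + bλ + c.

    Both roots lie strictly inside the unit circle iff 1+b+c > 0,
    1−b+c > 0 and |c| < 1.  Values within ``tol`` of a boundary give the
    verdict "marginal".
    """
    if not (math.isfinite(b) and math.isfinite(c)):
        raise ValueError("jury test requires finite coefficients")
    phi1 = 1.0 + b + c
    phim1 = 1.0 - b + c
    margins = (phi1, phim1, 1.0 - abs(c))
    boundary = any(abs(m) < tol for m in margins)
    if any(m < -tol for m in margins):
        verdict = "unstable"
    elif boundary:
        verdict = "marginal"
    else:
        verdict = "stable"
    return JuryTest(phi1, phim1, c, verdict, boundary)


def endemic_quadratic(params: ModelParameters) -> tuple[float, float]:
    """Coefficients (b, c) of the quadratic factor φ1(λ) = λ² + bλ + c."""
    eq = endemic_equilibrium(params)
    if eq is None:
        raise ValueError("no endemic equilibrium: R0 <= 1")
    Nstar = endemic_total_population(params)
    q = params.beta * eq.I / Nstar
    p = params.beta * eq.I * (eq.I + eq.R) / Nstar**2
    mu = params.mu
    b = -(2.0 - mu - q)
    c = (1.0 - mu) * (1.0 - q) + params.gamma * q + params.delta * p
    return b, c


def endemic_jacobian(params: ModelParameters) -> StabilityReport:
    """Linearization A1 at the endemic equilibrium in (N, I, R) coordinates.

    One eigenvalue is exactly 1−μ; the other two are the roots of the
    quadratic factor φ1, evaluated in closed form.  The Jury quantities
    φ1(1), φ1(−1) and the constant term are attached to the report.
    """
    eq = endemic_equilibrium(params)
    if eq is None:
        raise ValueError("no endemic equilibrium: R0 <= 1")
    Nstar = endemic_total_population(params)
    mu, gamma, delta = params.mu, params.gamma, params.delta
    q = params.beta * eq.I / Nstar
    p = params.beta * eq.I * (eq.I + eq.R) / Nstar**2
    A1 = np.array(
        [
            [1.0 - mu, -delta, 0.0],
            [p, 1.0 - q, -q],
            [0.0, gamma, 1.0 - mu],
        ]
    )
    b, c = endemic_quadratic(params)
    disc = complex(b * b - 4.0 * c) ** 0.5
    roots = np.array([(-b + disc) / 2.0, (-b - disc) / 2.0])
    eig = np.concatenate([[complex(1.0 - mu)], roots])
    rho = float(np.max(np.abs(eig)))
    jury = jury_quadratic_test(b, c)
    return StabilityReport(
        eq, A1, eig, rho, _verdict_from_radius(rho), jury=jury, coordinates="NIR"
    )


def classify_equilibria(params: ModelParameters) -> list[StabilityReport]:
    """Stability reports for every equilibrium present: E0 always, the
    endemic point when R0 > 1."""
    reports = [dfe_jacobian(params)]
    if basic_reproduction_number(params) > 1.0:
        reports.append(endemic_jacobian(params))
    return reports
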