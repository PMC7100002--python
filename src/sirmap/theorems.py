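"""Sufficient-condition checkers for the global dynamics of the SIR map.

Four analytic results govern the long-run behaviour:

* extinction: the disease-free equilibrium is globally asymptotically
  stable when R0 < 1 (and unstable when R0 > 1);
* persistence: when R0 > 1 the infective class stays bounded away from
  zero for any start with I(0) > 0;
* global endemic stability with δ = 0: sufficient conditions are
  R0 > (μ+γ)/μ and γ < μ;
* global endemic stability with δ ≥ 0: sufficient conditions are
  μ > δ+γ,  μ² > (μ+δ)(μ+δ+γ)²/(2+μ+δ+γ)  and
  max{(μ+δ+γ)/μ, δ/(μ−δ−γ)} < R0 < (1 + 2/(μ+δ+γ))·μ/(μ+δ).

These are sufficient, not necessary: a report whose verdict is False means
the condition set is silent, not that the equilibrium is unstable.  All
inequalities are strict; boundary equality yields "does not apply".
δ = 0 is tested as an exact structural zero.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import ModelParameters, basic_reproduction_number


@dataclass(frozen=True)
class Hypothesis:
    """One hypothesis of a theorem: human-readable text, the numeric
    value(s) it evaluates, and whether it holds."""

    expression: str
    value: object
    holds: bool


@dataclass(frozen=True)
class TheoremReport:
    theorem: int
    hypotheses: tuple[Hypothesis, ...]
    thresholds: dict

    @property
    def applies(self) -> bool:
        return all(h.holds for h in self.hypotheses)


def theorem1_applies(params: ModelParameters) -> TheoremReport:
    """Extinction condition: R0 < 1 (under the feasibility conditions)."""
    r0 = basic_reproduction_number(params)
    hyps = (
        Hypothesis(
            "beta+mu < 1 and mu+delta+gamma < 1",
            (params.beta + params.mu, params.exit_rate),
            params.feasible,
        ),
        Hypothesis("R0 < 1", r0, r0 < 1.0),
    )
    return TheoremReport(1, hyps, {"R0": r0})


def theorem2_applies(params: ModelParameters) -> TheoremReport:
    """Persistence condition: R0 > 1 (under the feasibility conditions)."""
    r0 = basic_reproduction_number(params)
    hyps = (
        Hypothesis(
            "beta+mu < 1 and mu+delta+gamma < 1",
            (params.beta + params.mu, params.exit_rate),
            params.feasible,
        ),
        Hypothesis("R0 > 1", r0, r0 > 1.0),
    )
    return TheoremReport(2, hyps, {"R0": r0})


def theorem4_applies(params: ModelParameters) -> TheoremReport:
    """Global endemic stability, δ = 0 case: R0 > (μ+γ)/μ and γ < μ."""
    r0 = basic_reproduction_number(params)
    mu, gamma = params.mu, params.gamma
    threshold = (mu + gamma) / mu if mu > 0 else float("inf")
    hyps = (
        Hypothesis("delta = 0", params.delta, params.delta == 0.0),
        Hypothesis("gamma < mu", (gamma, mu), gamma < mu),
        Hypothesis("R0 > (mu+gamma)/mu", (r0, threshold), r0 > threshold),
    )
    return TheoremReport(4, hyps, {"R0": r0, "r0_lower": threshold})


def theorem5_applies(params: ModelParameters) -> TheoremReport:
    """Global endemic stability, general δ case.

    Requires μ > δ+γ, the rate inequality
    μ² > (μ+δ)(μ+δ+γ)²/(2+μ+δ+γ), and R0 strictly inside
    (max{(μ+δ+γ)/μ, δ/(μ−δ−γ)},  (1 + 2/(μ+δ+γ))·μ/(μ+δ)).
    The term δ/(μ−δ−γ) is only evaluated when μ > δ+γ.
    """
    r0 = basic_reproduction_number(params)
    mu, delta, gamma = params.mu, params.delta, params.gamma
    e = params.exit_rate  # μ+δ+γ
    rates_ok = mu > delta + gamma
    quad_lhs = mu * mu
    quad_rhs = (mu + delta) * e * e / (2.0 + e)
    upper = (1.0 + 2.0 / e) * mu / (mu + delta) if e > 0 else float("inf")
    if rates_ok:
        lower = max(e / mu, delta / (mu - delta - gamma))
        window_ok = lower < r0 < upper
        window_val = (lower, r0, upper)
    else:
        lower = None
        window_ok = False
        window_val = (None, r0, upper)
    hyps = (
        Hypothesis("mu > delta + gamma", (mu, delta + gamma), rates_ok),
        Hypothesis(
            "mu^2 > (mu+delta)(mu+delta+gamma)^2 / (2+mu+delta+gamma)",
            (quad_lhs, quad_rhs),
            quad_lhs > quad_rhs,
        ),
        Hypothesis(
            "max{(mu+delta+gamma)/mu, delta/(mu-delta-gamma)} < R0 "
            "< (1 + 2/(mu+delta+gamma)) * mu/(mu+delta)",
            window_val,
            window_ok,
        ),
    )
    return TheoremReport(
        5,
        hyps,
        {
            "R0": r0,
            "r0_lower": lower,
            "r0_upper": upper,
            "rate_condition_lhs": quad_lhs,
            "rate_condition_rhs": quad_rhs,
        },
    )


def all_theorem_reports(params: ModelParameters) -> list[TheoremReport]:
    return [
        theorem1_applies(params),
        theorem2_applies(params),
        theorem4_applies(params),
        theorem5_applies(params),
    ]


def beta_interval_for_R0(
    params: ModelParameters, r0_low: float, r0_high: float
) -> tuple[float, float]:
    """β interval mapping onto a given R0 interval: β = R0·(μ+δ+γ).

    β is linear in R0, so the endpoints map directly.  The ``beta`` field
    of ``params`` is ignored.
    """
    if r0_low > r0_high:
        raise ValueError("r0_low must not exceed r0_high")
    if params.exit_rate <= 0:
        raise ValueError("beta interval requires mu + delta + gamma > 0")
    return (r0_low * params.exit_rate, r0_high * params.exit_rate)
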