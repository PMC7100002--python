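# Methods

## Model and assumptions

The package iterates a deterministic, real-valued three-compartment
difference-equation model with constant recruitment and standard
incidence.  Compartments are continuous non-negative reals, not integers:
the model describes expected population flows, not individual events.
Time is a dimensionless step (one day in the mumps scenario); all five
rates Λ, β, μ, δ, γ are per step.  The force-of-infection term βSI/N is
extended continuously by 0 at N = 0 (the numerator vanishes there, so this
is the unique continuous extension and avoids 0/0).

The internal time index starts at t = 0; scenario output can be relabelled
(the mumps application labels its first day t = 1, matching the convention
of the source data).

## Feasibility and the clipping policy

Non-negativity of solutions is guaranteed only when β+μ < 1 and
μ+δ+γ < 1 and the start lies in Ω1 = {S+I+R ≤ Λ/μ}.  `simulate` accepts
parameters outside this regime (they are needed to study the bifurcation
cascade, which lives at β > 1) but flags the run and, by default, clips
any component the raw map pushes below zero, counting and logging every
clipping event.

The bifurcation analysis in `sirmap.dynamics` deliberately iterates the
**raw** map instead.  On the cascade attractor the susceptible class
overshoots zero on alternate steps; clipping there is not a small
correction — it changes the attractor itself (numerically, the clipped map
stays on a period-2 orbit for all R0 up to at least 400, while the raw map
shows the full 1 → 2 → 4 → 8 → chaos cascade).  Since the object of study
in that regime is the unconstrained map as a dynamical system, period
detection and transition bisection default to `clip=False`.

## Equilibria and stability

Equilibrium coordinates are evaluated from the closed forms (see README)
and verified in tests against the stationarity equations (residuals below
1e-10 relative) and against long simulations.  Stability is assessed in
the transformed (N, I, R) coordinates, where the linearization's
characteristic polynomial factors exactly into (1−μ−λ) times a quadratic
φ1.  Eigenvalues are therefore computed from the factored form (exact and
fast); `numpy.linalg.eigvals` on the full matrix and a finite-difference
Jacobian of the original (S, I, R) map are retained as independent oracles
in the test suite — the two coordinate systems are related by an
invertible linear change of variables and must share a spectrum.

The Jury criterion for λ² + bλ + c (stable iff 1+b+c > 0, 1−b+c > 0,
|c| < 1) is implemented with a marginal band: any test quantity within
1e-9 of its boundary yields the verdict "marginal" rather than a forced
binary answer, and a quantity sitting exactly on a boundary is flagged
even when another quantity already decides instability.  The same 1e-9
band applies to the spectral-radius verdict, giving the bisection routines
a signed indicator.  The boundary case R0 = 1 is reported as "marginal"
without any claim about the dynamics there.

## Theorem-condition checkers

The global-stability and extinction/persistence condition sets are
evaluated with strict inequalities throughout; boundary equality means
"does not apply".  A False verdict is reported as the condition set being
silent, never as instability — the conditions are sufficient only, and the
tests include a regime (R0 between 1 and (μ+γ)/μ) where the checker is
silent yet simulation still converges to the endemic equilibrium.  δ = 0
is tested as an exact structural zero: scenario configurations must encode
structural zeros explicitly rather than as small numbers.  The general-δ
condition set uses the parse of the rate inequality
μ² > (μ+δ)(μ+δ+γ)²/(2+μ+δ+γ) that is consistent with its own δ=γ=0
reduction (μ > 0 and 1 < R0 < 1+2/μ) and with the benchmark values
1.7 and 107.86 it produces at (μ, δ, γ) = (0.01, 0.001, 0.006).

## Period detection and transition location

`detect_attractor_period` iterates a transient (default 5e4 steps — the
leading eigenvalues near criticality are within ~1e-2 of the unit circle,
so convergence onto the attractor is slow), then inspects a 512-step
window and reports the smallest period p ≤ 64 with
|I(t+p) − I(t)| < 1e-6·scale + 1e-9 throughout.  If the two window halves
disagree the point is labelled transitional and treated as the higher
period — conservative bracketing for the bisection.  Scan initial state is
the deterministic (S, I, R) = (0.9, 0.1, 0)·Λ/μ, inside Ω1; no randomness
enters the map, so scans are restartable and byte-reproducible.

Transitions are located two ways: `locate_stability_loss` brackets the
spectral radius of the endemic Jacobian crossing 1 (Brent, default xtol
1e-3 in R0; initial-condition-free), and `locate_period_doubling` bisects
on the detected attractor period (default tolerance 0.05 in R0).  At the
first flip the two instruments agree to well under 0.1 in R0.  At the
reference cascade rates (Λ=20, μ=0.01, γ=0.001, δ=0.001) the computed
transitions are R0 ≈ 184.52 (equilibrium → period 2) and R0 ≈ 223.80
(period 2 → 4); the 4 → 8 doubling falls between 232 and 233.

## Mumps scenario and β fitting

The scenario freezes the printed application constants (README).  μ is
assembled from the published demographic figures with the same rounding
the source used — annual deaths 7.06/1000 → daily 1.934e-5 (4 significant
figures) plus ageing-out 1/7300 → 1.37e-4 (3 significant figures) —
so the published μ = 0.00015634 is reproduced exactly; the unrounded sum
is exposed alongside.  A year is 365 steps (leap days ignored, matching
the rate conversions).  Annual cases sum the per-step incidence βSI/N over
consecutive 365-step blocks; partial trailing years are dropped and
logged.

The reported Chinese case counts are not shipped; `synthesize_incidence`
generates annual series from a known-β forward run, optionally with
independent Poisson noise per year (count data, no overdispersion
information available — the generator emulates reporting noise only, not
under-reporting, seasonality within the year, or demographic change, so
recovery results speak to estimator self-consistency rather than to real
surveillance data).  `fit_beta` minimizes the squared difference between
simulated and observed annual counts (counts at this scale are large and
roughly homoscedastic; a log-scale objective is available behind a flag).
Because the epidemic peak slides across year boundaries as β grows, the
SSE surface can develop secondary minima; the fit therefore runs a
25-point grid pre-search across the bounds and refines the bracketing
interval with bounded scalar minimization (xatol 1e-7).  A minimizer
within 0.1 % of a bound is flagged rather than raised.  Validation is by
parameter recovery: noiseless self-generated data returns the generating β
to 1e-4 across probes spanning [0.05, 0.12]; Poisson-noised data stays
within 2 % across seeds.

## Problem sizes in the tests

Unit tests use reduced draw counts and horizons (tens of draws, 1e4–3e4
steps) chosen so each property is still decisively exercised; the
end-to-end suite in `tests/test_acceptance.py` runs the full study sizes
(200 feasibility draws × 1e3 steps, 100 equilibrium draws, 1e4 random
quadratics, 1e5-step convergence runs from 10 starts, 5 noiseless probes
and 20 noise seeds for the β fit).

## Known limitations

* The model is deterministic and unstructured: no demographic noise, age
  structure, seasonality or vaccination.
* Global stability is corroborated empirically, never proved, by the
  simulation checks; the persistence floor is an observed minimum over a
  long window, not an analytic ε.
* Period detection resolves periods up to 64 at tolerance 1e-6; beyond
  the last reliably detected doubling the label "aperiodic" conflates
  long periods with chaos.
* In the cascade regime the raw map takes S transiently negative; results
  there describe the mathematical map, not an epidemiologically feasible
  trajectory.
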