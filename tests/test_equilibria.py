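"""Equilibria, Jacobians, Jury criterion and stability verdicts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sirmap as sm
from conftest import draw_feasible


class TestEquilibriumPoints:
    def test_disease_free_coordinates(self):
        p = sm.ModelParameters(20, 0.03, 0.01, 0, 0.006)
        eq = sm.disease_free_equilibrium(p)
        assert (eq.S, eq.I, eq.R) == (2000.0, 0.0, 0.0)
        zero = sm.disease_free_equilibrium(sm.ModelParameters(0, 0.03, 0.01, 0, 0.006))
        assert (zero.S, zero.I, zero.R) == (0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            sm.disease_free_equilibrium(sm.ModelParameters(20, 0.03, 0, 0, 0.006))

    def test_no_endemic_point_below_threshold(self):
        p = sm.ModelParameters(20, 0.01, 0.01, 0, 0.02)  # R0 = 1/3
        assert sm.endemic_equilibrium(p) is None
        at_threshold = sm.ModelParameters(20, 0.016, 0.01, 0, 0.006)  # R0 = 1
        assert sm.endemic_equilibrium(at_threshold) is None

    def test_delta0_closed_forms(self, params_delta0):
        """With δ=0: I* = Λ(R0−1)/β, S* = Λ(μ+γ)/(μβ), N* = Λ/μ."""
        p = params_delta0
        eq = sm.endemic_equilibrium(p)
        r0 = sm.basic_reproduction_number(p)
        assert eq.I == pytest.approx(p.Lambda * (r0 - 1) / p.beta, rel=1e-12)
        assert eq.S == pytest.approx(p.Lambda * (p.mu + p.gamma) / (p.mu * p.beta),
                                     rel=1e-12)
        assert eq.R == pytest.approx(350.0, rel=1e-12)
        assert sm.endemic_total_population(p) == pytest.approx(
            p.carrying_capacity, rel=1e-12)
        assert eq.N == pytest.approx(p.carrying_capacity, rel=1e-12)

    def test_long_simulation_converges_to_endemic_point(self, params_delta0):
        eq = sm.endemic_equilibrium(params_delta0)
        traj = sm.simulate(sm.EpidemicState(1500, 100, 10), params_delta0,
                           20_000)
        np.testing.assert_allclose(
            traj.states[-1], (eq.S, eq.I, eq.R), rtol=1e-8)

    def test_stationarity_residuals_random_draws(self, rng):
        """Both fixed points satisfy their defining equations to < 1e-10."""
        checked = 0
        while checked < 100:
            p, _ = draw_feasible(rng, r0_below_one=False)
            eq = sm.endemic_equilibrium(p)
            assert eq is not None and eq.I > 0
            scale = max(eq.N, 1.0)
            foi = p.beta * eq.S * eq.I / eq.N
            assert abs(p.Lambda - foi - p.mu * eq.S) < 1e-10 * scale
            assert abs(p.beta * eq.S / eq.N - p.exit_rate) < 1e-10
            assert abs(p.gamma * eq.I - p.mu * eq.R) < 1e-10 * scale
            dfe = sm.disease_free_equilibrium(p)
            stepped = sm.step(dfe.as_state(), p)
            assert stepped.S == pytest.approx(dfe.S, rel=1e-10)
            checked += 1

    def test_endemic_branch_continuous_at_threshold(self):
        """I* → 0 as R0 → 1+."""
        base = sm.ModelParameters(20, 1.0, 0.01, 0.001, 0.006)
        sizes = [sm.endemic_equilibrium(base.with_r0(1 + eps)).I
                 for eps in (1e-2, 1e-4, 1e-6)]
        assert sizes[0] > sizes[1] > sizes[2]
        # I* ≈ Λ/(μ+γ) · (R0−1) near the threshold: linear vanishing
        assert sizes[2] == pytest.approx(sizes[1] * 1e-2, rel=0.02)
        assert sizes[2] < 2e-3


class TestDfeJacobian:
    def test_eigenvalues_exact(self):
        p = sm.ModelParameters(20, 0.01, 0.01, 0, 0.02)  # R0 = 1/3
        rep = sm.dfe_jacobian(p)
        lams = sorted(rep.eigenvalues.real)
        assert lams == pytest.approx([0.98, 0.99, 0.99], abs=1e-15)
        assert rep.verdict == "stable"
        oracle = np.sort(np.abs(np.linalg.eigvals(rep.jacobian)))
        np.testing.assert_allclose(np.sort(np.abs(rep.eigenvalues)), oracle,
                                   atol=1e-12)

    def test_unstable_above_threshold(self, params_delta0):
        rep = sm.dfe_jacobian(params_delta0)  # R0 = 1.875
        assert rep.verdict == "unstable"
        assert max(rep.eigenvalues.real) > 1

    def test_degenerate_rates(self):
        p = sm.ModelParameters(20, 0.0, 0.05, 0.0, 0.0)
        rep = sm.dfe_jacobian(p)
        np.testing.assert_allclose(rep.eigenvalues.real, 0.95, atol=1e-15)


class TestEndemicJacobian:
    def test_stable_benchmark(self, params_delta):
        rep = sm.endemic_jacobian(params_delta)  # R0 ≈ 1.765
        assert rep.verdict == "stable"
        assert rep.jury.stable
        assert rep.jury.phi_at_1 > 0 and rep.jury.phi_at_minus1 > 0
        assert abs(rep.jury.constant) < 1

    def test_factored_eigenvalue_present(self, params_delta):
        rep = sm.endemic_jacobian(params_delta)
        assert min(abs(rep.eigenvalues - (1 - params_delta.mu))) < 1e-9

    def test_matches_generic_eigensolver(self, rng):
        for _ in range(20):
            p, _ = draw_feasible(rng, r0_below_one=False)
            rep = sm.endemic_jacobian(p)
            oracle = np.sort(np.abs(np.linalg.eigvals(rep.jacobian)))
            np.testing.assert_allclose(np.sort(np.abs(rep.eigenvalues)),
                                       oracle, atol=1e-8)

    def test_sir_and_nir_coordinates_share_spectrum(self, rng):
        """The (S,I,R) and (N,I,R) linearizations are similar matrices."""
        for _ in range(20):
            p, _ = draw_feasible(rng, r0_below_one=False)
            eq = sm.endemic_equilibrium(p)
            J = sm.sir_jacobian(p, eq.as_state())
            nir = sm.endemic_jacobian(p).jacobian
            np.testing.assert_allclose(
                np.sort(np.abs(np.linalg.eigvals(J))),
                np.sort(np.abs(np.linalg.eigvals(nir))),
                rtol=1e-8, atol=1e-10,
            )

    def test_sir_jacobian_matches_finite_differences(self, params_delta):
        p = params_delta
        state = sm.EpidemicState(900, 300, 120)
        J = sm.sir_jacobian(p, state)

        def f(x):
            return np.array(sm.step(sm.EpidemicState(*x), p).as_tuple())

        x0 = np.array(state.as_tuple())
        num = np.empty((3, 3))
        for j in range(3):
            h = 1e-6 * max(1.0, abs(x0[j]))
            e = np.zeros(3)
            e[j] = h
            num[:, j] = (f(x0 + e) - f(x0 - e)) / (2 * h)
        np.testing.assert_allclose(J, num, rtol=1e-6, atol=1e-8)

    def test_requires_supercritical_r0(self):
        p = sm.ModelParameters(20, 0.01, 0.01, 0, 0.02)
        with pytest.raises(ValueError):
            sm.endemic_jacobian(p)

    def test_unstable_in_cascade_regime(self, cascade_rates):
        rep = sm.endemic_jacobian(cascade_rates.with_r0(200))
        assert rep.verdict == "unstable"
        oracle = max(abs(np.linalg.eigvals(rep.jacobian)))
        assert rep.spectral_radius == pytest.approx(oracle, rel=1e-10)
        assert oracle > 1


class TestJuryCriterion:
    def test_examples(self):
        stable = sm.jury_quadratic_test(-0.5, 0.04)  # roots 0.1, 0.4
        assert stable.verdict == "stable" and not stable.boundary
        unstable = sm.jury_quadratic_test(-3.0, 2.0)  # roots 1, 2
        assert unstable.verdict == "unstable"
        assert unstable.boundary  # phi(1) = 0 exactly
        assert unstable.phi_at_1 == pytest.approx(0.0, abs=1e-15)
        with pytest.raises(ValueError):
            sm.jury_quadratic_test(float("inf"), 0.0)

    def test_agrees_with_root_moduli(self, rng):
        """Verdict ≡ max-root-modulus check on random quadratics."""
        b = rng.uniform(-3, 3, size=2000)
        c = rng.uniform(-3, 3, size=2000)
        for bi, ci in zip(b, c):
            roots = np.roots([1.0, bi, ci])
            rho = max(abs(roots))
            verdict = sm.jury_quadratic_test(bi, ci).verdict
            if abs(rho - 1) < 1e-9:
                continue  # measure-zero boundary
            assert verdict == ("stable" if rho < 1 else "unstable"), (bi, ci)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(b=st.floats(-3, 3), c=st.floats(-3, 3))
    def test_agrees_with_root_moduli_hypothesis(self, b, c):
        rho = max(abs(np.roots([1.0, b, c])))
        if abs(rho - 1) < 1e-9:
            return
        assert sm.jury_quadratic_test(b, c).stable == (rho < 1)


class TestClassification:
    def test_subcritical_single_report(self):
        p = sm.ModelParameters(20, 0.01, 0.01, 0, 0.02)
        reports = sm.classify_equilibria(p)
        assert len(reports) == 1
        assert reports[0].equilibrium.kind == "disease_free"
        assert reports[0].verdict == "stable"

    def test_supercritical_pair(self, params_delta):
        reports = sm.classify_equilibria(params_delta)
        assert [r.equilibrium.kind for r in reports] == ["disease_free",
                                                         "endemic"]
        assert reports[0].verdict == "unstable"
        assert reports[1].verdict == "stable"

    def test_jury_margins_positive_for_feasible_supercritical(self, rng):
        for _ in range(50):
            p, _ = draw_feasible(rng, r0_below_one=False)
            jury = sm.endemic_jacobian(p).jury
            assert jury.phi_at_1 > 0
            assert jury.phi_at_minus1 > 0
            assert jury.constant < 1
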