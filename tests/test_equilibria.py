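"""Contagion-free and endemic equilibria, closed forms and root finding."""

import numpy as np
import pytest

from coexdyn import (
    ModelId,
    NoEndemicEquilibrium,
    coexistence_endemic_equilibrium,
    corruption_endemic_equilibrium,
    disease_free_equilibrium,
    racism_endemic_equilibrium,
    rhs,
    scenario,
    reference_parameters,
)
from coexdyn.equilibria import residual_tolerance
from coexdyn.simulate import integrate_to_steady_state


def bisection_endemic_force(model: ModelId, p) -> list[float]:
    """Independent scalar-equation oracle for the submodel endemic force.

    For a trial force value lam the remaining balance equations are linear in
    the three active compartments; solving them and re-evaluating the force
    gives a fixed-point defect whose positive roots are the endemic forces.
    Roots are located by sign changes on a fine grid plus brentq refinement.
    """
    from scipy.optimize import brentq

    if model is ModelId.RACISM:
        def defect(lam):
            A = np.array([
                [-(lam + p.mu), 0.0, p.theta2],
                [lam, -(p.gamma2 + p.mu), 0.0],
                [0.0, p.gamma2, -(p.theta2 + p.mu)],
            ])
            S, R, R2 = np.linalg.solve(A, [-p.Lambda, 0.0, 0.0])
            return p.alpha * R - lam
        lam_max = p.alpha * p.Lambda / p.mu
    else:
        def defect(lam):
            A = np.array([
                [-(lam + p.mu), 0.0, p.theta1],
                [lam, -(p.gamma1 + p.mu), 0.0],
                [0.0, p.gamma1, -(p.theta1 + p.mu)],
            ])
            S, C, R1 = np.linalg.solve(A, [-p.Lambda, 0.0, 0.0])
            N = S + C + R1
            return (p.beta * C / N if N > 0 else 0.0) - lam
        lam_max = p.beta
    grid = np.linspace(1e-12, lam_max * 1.001, 2001)
    vals = np.array([defect(g) for g in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(defect, grid[i], grid[i + 1], xtol=1e-14))
    return roots


class TestContagionFree:
    @pytest.mark.parametrize("Lambda, mu, S0", [(50.0, 0.01, 5000.0), (1.0, 0.1, 10.0)])
    def test_susceptible_pool_is_recruitment_over_removal(self, Lambda, mu, S0, ref_params):
        p = ref_params.replace(Lambda=Lambda, mu=mu)
        eq = disease_free_equilibrium(ModelId.FULL, p)
        assert eq.state[0] == S0 and np.all(eq.state[1:] == 0)
        assert eq.residual == 0.0


class TestRacismEndemic:
    def test_toy_closed_form(self, toy_racism):
        eq = racism_endemic_equilibrium(toy_racism)
        assert eq.force_of_infection.lambda_R == pytest.approx(2.0 / 15.0, rel=1e-12)
        assert eq.state[0] == pytest.approx(5.0, rel=1e-12)
        assert eq.state[2] == pytest.approx(10.0 / 3.0, rel=1e-12)
        assert eq.state[5] == pytest.approx(5.0 / 3.0, rel=1e-12)
        assert eq.residual <= 1e-9

    def test_below_threshold_is_an_error(self, toy_racism):
        with pytest.raises(NoEndemicEquilibrium):
            racism_endemic_equilibrium(toy_racism.replace(alpha=0.01))

    def test_continuity_at_threshold(self, toy_racism):
        # R_r -> 1+ : force -> 0 and the state collapses onto the
        # contagion-free point
        alpha_crit = toy_racism.mu * (toy_racism.gamma2 + toy_racism.mu) / toy_racism.Lambda
        p = toy_racism.replace(alpha=alpha_crit * (1 + 1e-8))
        eq = racism_endemic_equilibrium(p)
        assert eq.force_of_infection.lambda_R < 1e-8
        dfe = disease_free_equilibrium(ModelId.RACISM, p)
        assert np.allclose(eq.state, dfe.state, rtol=1e-6, atol=1e-6)

    def test_population_partition_and_oracle(self, rng):
        for _ in range(20):
            p = reference_parameters(alpha=10 ** rng.uniform(-5.4, -4.0), beta=0.0)
            eq = racism_endemic_equilibrium(p)
            total = eq.state.sum()
            assert total == pytest.approx(p.Lambda / p.mu, rel=1e-10)
            assert np.max(np.abs(rhs(ModelId.RACISM, eq.state, p))) <= residual_tolerance(p)
            roots = bisection_endemic_force(ModelId.RACISM, p)
            assert len(roots) == 1
            assert roots[0] == pytest.approx(eq.force_of_infection.lambda_R, rel=1e-8)


class TestCorruptionEndemic:
    def test_toy_closed_form(self, toy_corruption):
        eq = corruption_endemic_equilibrium(toy_corruption)
        assert eq.force_of_infection.lambda_C == pytest.approx(2.0 / 15.0, rel=1e-12)
        assert eq.state[0] == pytest.approx(5.0, rel=1e-12)
        assert eq.state[1] == pytest.approx(10.0 / 3.0, rel=1e-12)
        assert eq.state[4] == pytest.approx(5.0 / 3.0, rel=1e-12)
        assert eq.residual <= 1e-9

    def test_below_threshold_is_an_error(self):
        p = reference_parameters(alpha=0.0, beta=0.4).replace(gamma1=0.5, mu=0.1)
        with pytest.raises(NoEndemicEquilibrium):
            corruption_endemic_equilibrium(p)

    def test_fast_relapse_limit(self, toy_corruption):
        # theta1 -> infinity: recovery gives no lasting protection and the
        # force approaches (gamma1+mu)(R_c - 1)
        p = toy_corruption.replace(theta1=1e9)
        eq = corruption_endemic_equilibrium(p)
        r = p.beta / (p.gamma1 + p.mu)
        assert eq.force_of_infection.lambda_C == pytest.approx(
            (p.gamma1 + p.mu) * (r - 1), rel=1e-6
        )

    def test_population_partition_and_oracle(self, rng):
        for _ in range(20):
            p = reference_parameters(alpha=0.0, beta=rng.uniform(0.02, 1.5))
            eq = corruption_endemic_equilibrium(p)
            assert eq.state.sum() == pytest.approx(p.Lambda / p.mu, rel=1e-10)
            assert np.max(np.abs(rhs(ModelId.CORRUPTION, eq.state, p))) <= residual_tolerance(p)
            roots = bisection_endemic_force(ModelId.CORRUPTION, p)
            assert len(roots) == 1
            assert roots[0] == pytest.approx(eq.force_of_infection.lambda_C, rel=1e-8)

    @pytest.mark.parametrize("model", [ModelId.RACISM, ModelId.CORRUPTION])
    def test_oracle_finds_no_root_below_threshold(self, model):
        p = reference_parameters(alpha=1e-6, beta=0.005)
        assert bisection_endemic_force(model, p) == []


class TestCoexistence:
    def test_decoupled_corruption_limit(self, toy_corruption):
        res = coexistence_endemic_equilibrium(toy_corruption, seed=0)
        assert not res.found
        assert res.racism_boundary is None
        emb = res.corruption_boundary
        ref = corruption_endemic_equilibrium(toy_corruption)
        assert np.allclose(emb.state, ref.state, rtol=1e-10)
        assert emb.residual <= residual_tolerance(toy_corruption)

    def test_decoupled_racism_limit(self, toy_racism):
        res = coexistence_endemic_equilibrium(toy_racism, seed=0)
        assert not res.found
        assert res.corruption_boundary is None
        ref = racism_endemic_equilibrium(toy_racism)
        assert np.allclose(res.racism_boundary.state, ref.state, rtol=1e-10)

    def test_supercritical_interior_matches_long_time_limit(self):
        p, init = scenario(42, "supercritical")
        res = coexistence_endemic_equilibrium(p, seed=42)
        assert res.found
        assert res.interior.residual <= residual_tolerance(p)
        assert np.all(res.interior.state > 0)
        traj = integrate_to_steady_state(ModelId.FULL, p, init, tol=1e-9)
        rel = np.max(
            np.abs(traj.states[-1] - res.interior.state)
            / np.maximum(np.abs(res.interior.state), 1e-12)
        )
        assert rel <= 1e-4
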