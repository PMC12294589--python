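import math

import numpy as np
import pytest

from fklpi.errors import ContinuationRangeError, InvalidParameterError
from fklpi.fk_core import (
    FKProfile,
    ThermalSystem,
    alpha_parameter,
    centroid_log_weight,
    centroid_potential,
    effective_frequency_matrix,
    quantum_widths,
    smeared_hessian_force_sampling,
    smeared_hessian_quadrature,
    smearing_width,
    solve_effective_frequency,
)
from fklpi.potentials import make_model_potential

SYS1 = ThermalSystem(beta=1.0, masses=[1.0])


class TestAlpha:
    def test_closed_form_value(self):
        # hbar*Omega*beta = 2 -> coth(1) - 1
        s = ThermalSystem(beta=2.0, masses=[1.0])
        assert alpha_parameter(1.0, s) == pytest.approx(
            1.0 / math.tanh(1.0) - 1.0, abs=1e-12)
        assert alpha_parameter(1.0, s) == pytest.approx(0.31304, abs=5e-6)

    def test_low_temperature_limit(self):
        # alpha - 1 = -2/(hbar*Omega*beta) + O(exp(-x))
        s = ThermalSystem(beta=1e7, masses=[1.0])
        assert alpha_parameter(1.0, s) == pytest.approx(1.0, abs=1e-6)

    def test_high_temperature_series(self):
        s = ThermalSystem(beta=1e-4, masses=[1.0])
        assert alpha_parameter(1.0, s) == pytest.approx(1e-4 / 6, rel=1e-8)

    def test_range(self):
        for x in (0.01, 0.5, 3.0, 40.0):
            s = ThermalSystem(beta=x, masses=[1.0])
            a = alpha_parameter(1.0, s)
            assert 0 < a < 1

    def test_rejects_barrier(self):
        with pytest.raises(InvalidParameterError):
            alpha_parameter(-1.0, SYS1)


class TestSmearingWidth:
    def test_closed_form_value(self):
        assert smearing_width(1.0, SYS1) == pytest.approx(
            0.5 / math.tanh(0.5) - 1.0, abs=1e-12)

    def test_high_temperature_limit(self):
        s = ThermalSystem(beta=1e-3, masses=[1.0])
        assert smearing_width(1.0, s) == pytest.approx(
            s.hbar**2 * s.beta / 12, rel=1e-6)

    def test_ground_state_width_limit(self):
        s = ThermalSystem(beta=1e6, masses=[1.0])
        # a^2 -> hbar/(2 M Omega)
        assert smearing_width(4.0, s) == pytest.approx(1.0 / (2 * 2.0), rel=1e-5)

    def test_continuity_across_zero_frequency(self):
        lim = SYS1.hbar**2 * SYS1.beta / 12
        assert smearing_width(1e-9, SYS1) == pytest.approx(lim, rel=1e-8)
        assert smearing_width(-1e-9, SYS1) == pytest.approx(lim, rel=1e-8)

    def test_barrier_branch_positive_within_window(self):
        for x in (0.5, 2.0, 5.0, 6.2):  # hbar|Omega|beta values < 2 pi
            s = ThermalSystem(beta=x, masses=[1.0])
            assert smearing_width(-1.0, s) > 0

    def test_barrier_out_of_range(self):
        s = ThermalSystem(beta=2 * math.pi + 1e-6, masses=[1.0])
        with pytest.raises(ContinuationRangeError):
            smearing_width(-1.0, s)


class TestSmearedHessian:
    def test_harmonic_constant_integrand(self):
        m = make_model_potential("harmonic", {"mass": 1.0, "omega": 1.4})
        for a2 in (0.01, 0.5, 3.0):
            assert smeared_hessian_quadrature(m, 0.3, a2) == pytest.approx(
                1.4**2, rel=1e-12)

    def test_quartic_gaussian_second_moment(self):
        m = make_model_potential("quartic", {"c": 1.0})
        assert smeared_hessian_quadrature(m, 0.0, 0.7) == pytest.approx(
            3 * 0.7, rel=1e-12)

    def test_double_well_at_barrier_top(self):
        m = make_model_potential("double_well", {"a": 1.0, "b": 1.0})
        assert smeared_hessian_quadrature(m, 0.0, 1.0) == pytest.approx(2.0)

    def test_force_sampling_unbiased_harmonic(self):
        m = make_model_potential("harmonic", {"mass": 1.0, "omega": 1.0})
        est, sem = smeared_hessian_force_sampling(m, 0.0, 0.3, 5000, 11)
        # per-sample values are omega^2 y^2/a2 (chi^2_1): mean omega^2, var 2
        assert est == pytest.approx(1.0, abs=3 * sem)
        assert sem == pytest.approx(math.sqrt(2.0 / 5000), rel=0.1)

    def test_force_sampling_matches_quadrature_morse(self):
        m = make_model_potential("morse", {"D": 1.0, "a": 1.0})
        quad = smeared_hessian_quadrature(m, 0.2, 0.4)
        est, sem = smeared_hessian_force_sampling(m, 0.2, 0.4, 20_000, 5)
        assert abs(est - quad) < 3 * sem

    def test_needs_two_samples(self):
        m = make_model_potential("harmonic", {"mass": 1.0, "omega": 1.0})
        with pytest.raises(InvalidParameterError):
            smeared_hessian_force_sampling(m, 0.0, 0.1, 1)


class TestSelfConsistentSolve:
    def test_harmonic_converges_immediately(self):
        m = make_model_potential("harmonic", {"mass": 1.0, "omega": 2.0})
        r = solve_effective_frequency(m, 1.3, SYS1)
        assert r.converged and r.iterations == 1
        assert r.omega2 == pytest.approx(4.0, rel=1e-12)

    def test_quartic_fixed_point_against_scan(self):
        """The converged Omega^2 solves Omega^2 = 3 a^2(Omega) (dense scan)."""
        m = make_model_potential("quartic", {"c": 1.0})
        r = solve_effective_frequency(m, 0.0, SYS1, tol=1e-10)
        # independent scalar-root oracle by bisection on g(w) = w - 3 a^2(w)
        def g(w):
            return w - 3.0 * smearing_width(w, SYS1)
        lo, hi = 1e-6, 10.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if g(lo) * g(mid) <= 0:
                hi = mid
            else:
                lo = mid
        assert r.omega2 == pytest.approx(0.5 * (lo + hi), rel=1e-6)

    @pytest.mark.parametrize("name,params,xc", [
        ("quartic", {"c": 1.0}, 0.0),
        ("morse", {"D": 1.0, "a": 1.0}, 0.1),
        ("double_well", {"a": 1.0, "b": 1.0}, 1.0),
    ])
    def test_iteration_economy(self, name, params, xc):
        m = make_model_potential(name, params)
        r = solve_effective_frequency(m, xc, SYS1, tol=1e-8)
        assert r.converged
        assert r.iterations <= 10

    def test_force_sampling_mode_runs(self):
        m = make_model_potential("morse", {"D": 2.0, "a": 0.8})
        r = solve_effective_frequency(m, 0.0, SYS1, smearing="force_sampling",
                                      n_force_samples=4000, rng=9, tol=1e-3)
        rq = solve_effective_frequency(m, 0.0, SYS1)
        assert r.converged
        assert r.omega2 == pytest.approx(rq.omega2, rel=0.05)


class TestCentroidPotential:
    def test_harmonic_closed_form(self):
        m = make_model_potential("harmonic", {"mass": 1.0, "omega": 1.5})
        s = ThermalSystem(beta=3.0, masses=[1.0])
        for xc in (-1.0, 0.0, 2.0):
            r = solve_effective_frequency(m, xc, s)
            x = 1.5 * 3.0
            expect = (math.log(math.sinh(0.5 * x) / (0.5 * x)) / 3.0
                      + 0.5 * 1.5**2 * xc**2)
            assert r.W1 == pytest.approx(expect, abs=1e-10)

    def test_free_particle(self):
        free = make_model_potential("external", {
            "func": lambda x: (0.0, np.zeros_like(x)), "dimension": 1,
            "hessian_func": lambda x: np.zeros((1, 1))})
        r = solve_effective_frequency(free, 0.7, SYS1)
        assert r.omega2 == pytest.approx(0.0, abs=1e-12)
        assert r.W1 == pytest.approx(0.0, abs=1e-12)
        assert r.a2 == pytest.approx(SYS1.hbar**2 * SYS1.beta / 12, rel=1e-10)

    def test_classical_limit(self):
        m = make_model_potential("harmonic", {"mass": 1.0, "omega": 1.0})
        xc = 3.0
        err = {}
        for beta in (1e-3, 1e-4):
            s = ThermalSystem(beta=beta, masses=[1.0])
            r = solve_effective_frequency(m, xc, s)
            err[beta] = abs(r.W1 - m.value([xc])) / m.value([xc])
        assert err[1e-4] < 1e-6
        # error vanishes linearly in beta (quantum corrections ~ hbar^2 w^2 beta)
        assert err[1e-3] / err[1e-4] == pytest.approx(10, rel=0.2)

    def test_barrier_branch_sin_form(self):
        pb = make_model_potential("parabolic_barrier", {"mass": 1.0, "omega_b": 1.0})
        s = ThermalSystem(beta=2.0, masses=[1.0])
        r = solve_effective_frequency(pb, 0.0, s)
        th = 0.5 * 2.0  # hbar*|Omega|*beta/2
        ln_term = math.log(math.sin(th) / th) / 2.0
        vs = -0.5 * r.a2  # smeared V at xc=0 for the inverted parabola
        half = 0.5 * (-1.0) * r.a2
        assert r.W1 == pytest.approx(ln_term + vs - half, abs=1e-10)


class TestCentroidWeight:
    def test_free_particle_weight_uniform(self):
        assert centroid_log_weight(0.0, 0.5, 0.0, SYS1) == \
            centroid_log_weight(5.0, 0.5, 0.0, SYS1)

    def test_constant_shift_cancels_in_differences(self):
        lw1 = centroid_log_weight(1.0, 0.2, 3.0, SYS1) - \
            centroid_log_weight(2.0, 0.2, 5.0, SYS1)
        lw2 = centroid_log_weight(1.0, 0.2, 13.0, SYS1) - \
            centroid_log_weight(2.0, 0.2, 15.0, SYS1)
        assert lw1 == pytest.approx(lw2)

    def test_harmonic_implied_moments(self):
        """Gaussian moments of exp(-beta W1): <xc^2> = 1/(beta M w^2)."""
        m = make_model_potential("harmonic", {"mass": 1.0, "omega": 1.2})
        s = ThermalSystem(beta=2.5, masses=[1.0])
        xs = np.linspace(-6, 6, 4001)
        w1 = np.array([solve_effective_frequency(m, x, s).W1 for x in xs[::40]])
        xq = xs[::40]
        w = np.exp(-s.beta * (w1 - w1.min()))
        x2 = np.trapezoid(xq**2 * w, xq) / np.trapezoid(w, xq)
        assert x2 == pytest.approx(1.0 / (2.5 * 1.2**2), rel=1e-4)


def test_quartic_width_monotone_in_beta():
    m = make_model_potential("quartic", {"c": 1.0})
    a2s = []
    for beta in (4.0, 2.0, 1.0, 0.5, 0.25):
        s = ThermalSystem(beta=beta, masses=[1.0])
        a2s.append(solve_effective_frequency(m, 0.0, s).a2)
    assert all(x > y for x, y in zip(a2s, a2s[1:]))


class TestEffectiveFrequencyMatrix:
    def test_uncoupled_harmonic_exact(self):
        m = make_model_potential("harmonic", {"mass": [1.0, 2.0],
                                              "omega": [1.0, 2.5]})
        s = ThermalSystem(beta=1.5, masses=[1.0, 2.0])
        r = effective_frequency_matrix(m, [0.3, -0.2], s, rng=0)
        assert r.converged
        assert np.allclose(np.sort(r.omega2), [1.0, 6.25], rtol=1e-10)

    @pytest.mark.parametrize("beta", [0.3, 5.0])
    def test_bilinear_coupling_any_temperature(self, beta):
        K = np.array([[2.0, 0.5], [0.5, 1.0]])
        m = make_model_potential("external", {
            "func": lambda x: (0.5 * x @ K @ x, K @ x),
            "hessian_func": lambda x: K, "dimension": 2})
        s = ThermalSystem(beta=beta, masses=[1.0, 1.0])
        r = effective_frequency_matrix(m, [0.1, 0.4], s, rng=0)
        assert np.allclose(np.sort(r.omega2), np.linalg.eigvalsh(K), rtol=1e-10)

    def test_dimer_reduces_to_relative_coordinate(self):
        """Matrix solver on the LJ dimer: zero translational mode with the
        free-particle width, vibrational mode matching the 1D solver on the
        relative coordinate (reduced mass m/2)."""
        dm = make_model_potential("pair_liquid", {
            "n_particles": 2, "box_length": 20.0, "epsilon": 1.0, "sigma": 1.0})
        s2 = ThermalSystem(beta=4.0, masses=[1.0, 1.0])
        r = effective_frequency_matrix(dm, [0.0, 2 ** (1 / 6)], s2, rng=1,
                                       n_samples=4000, tol=1e-5)
        lam = np.sort(r.omega2)
        k_zero = int(np.argmin(np.abs(r.omega2)))
        assert abs(lam[0]) < 1e-6 * lam[1]
        assert r.a2[k_zero] == pytest.approx(4.0 / 12, rel=1e-10)
        rel = make_model_potential("external", {
            "func": lambda x: (float(dm._u(abs(x[0]))),
                               np.array([float(dm._du(abs(x[0])) * np.sign(x[0]))])),
            "dimension": 1})
        rr = solve_effective_frequency(rel, 2 ** (1 / 6),
                                       ThermalSystem(beta=4.0, masses=[0.5]))
        # Monte Carlo smearing of the strongly anharmonic LJ wall: agreement
        # at the level of the sampling error
        assert lam[1] == pytest.approx(rr.omega2, rel=0.10)


class TestFKProfile:
    def test_matches_direct_solve(self, harmonic_model, harmonic_system,
                                  harmonic_profile):
        for x in (-1.3, 0.0, 2.1):
            r = solve_effective_frequency(harmonic_model, x, harmonic_system)
            assert harmonic_profile.W1(x) == pytest.approx(r.W1, abs=1e-9)
            assert harmonic_profile.omega2(x) == pytest.approx(r.omega2, rel=1e-8)

    def test_transparent_extension(self, harmonic_model, harmonic_system):
        p = FKProfile(harmonic_model, harmonic_system, -2, 2, n_points=41)
        val = p.W1(5.0)  # outside the initial grid
        r = solve_effective_frequency(harmonic_model, 5.0, harmonic_system)
        assert val == pytest.approx(r.W1, rel=1e-6)

    def test_invalid_gap_detected_for_deep_double_well(self):
        """A deep double well at low T has a barrier window where the
        continuation leaves its validity range; queries there must fail."""
        m = make_model_potential("double_well", {"a": 1.0, "b": 0.1})
        s = ThermalSystem(beta=8.0, masses=[1.0])
        p = FKProfile(m, s, -6, 6, n_points=121)
        assert len(p.segments) == 2
        assert p.try_W1(0.0) is None
        with pytest.raises(ContinuationRangeError):
            p.W1(0.0)

    def test_low_temperature_benchmark_well_is_fully_valid(
            self, double_well_model, double_well_system):
        p = FKProfile(double_well_model, double_well_system, -3, 3, n_points=61)
        assert len(p.segments) == 1
        assert np.all(p.valid)
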