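import math

import numpy as np
import pytest

from fklpi.correlation import (
    CorrelationSeries,
    classical_wigner_correlation,
    diffusion_from_vacf,
    ensemble_moment_series,
    harmonic_qcf,
    intermediate_scattering,
    kubo_correlation,
    planetary_correlation,
    qcf_ratio,
    radial_distribution,
    spectrum_from_cf,
)
from fklpi.errors import GridError, InvalidParameterError
from fklpi.exact_reference import (
    harmonic_kubo_position_cf,
    harmonic_position_cf,
)
from fklpi.fk_core import ThermalSystem

from conftest import exact_x2

DT, NSTEPS = 0.05, 200


@pytest.fixture(scope="module")
def harmonic_cfs(harmonic_model, harmonic_system, harmonic_ensemble):
    ens, planets = harmonic_ensemble
    std = classical_wigner_correlation(
        harmonic_model, harmonic_system, "position", "position", ens, planets,
        DT, NSTEPS)
    kub = kubo_correlation(harmonic_model, harmonic_system, "position", ens,
                           planets, DT, NSTEPS)
    return std, kub


class TestHarmonicClosedForms:
    def test_standard_position_cf(self, harmonic_cfs, harmonic_system):
        std, _ = harmonic_cfs
        exact = harmonic_position_cf(std.times, 1.0, harmonic_system)
        # seeded run: check representative points at 3 sigma
        for k in (0, 25, 50, 100, 150, 200):
            assert abs(std.values[k] - exact[k]) < 3 * max(std.stderr[k], 1e-4)

    def test_t0_is_quantum_x2(self, harmonic_cfs, harmonic_system):
        std, _ = harmonic_cfs
        x2 = exact_x2(harmonic_system.beta)
        assert abs(std.values[0].real - x2) < 3 * std.stderr[0]
        assert std.values[0].imag == pytest.approx(0.0, abs=3 * std.stderr[0])

    def test_kubo_position_cf(self, harmonic_cfs, harmonic_system):
        _, kub = harmonic_cfs
        exact = harmonic_kubo_position_cf(kub.times, 1.0, harmonic_system)
        for k in (0, 25, 50, 100, 200):
            assert abs(kub.values[k] - exact[k]) < 3 * max(kub.stderr[k], 1e-4)
        assert kub.values[0].real == pytest.approx(
            1.0 / harmonic_system.beta, abs=3 * kub.stderr[0])

    def test_kubo_momentum_cf(self, harmonic_model, harmonic_system,
                              harmonic_ensemble):
        """<p(0)p(t)>_K = (M/beta) cos wt for the harmonic oscillator."""
        ens, planets = harmonic_ensemble
        cf = kubo_correlation(harmonic_model, harmonic_system, "momentum",
                              ens, planets, DT, NSTEPS)
        exact = np.cos(cf.times) / harmonic_system.beta
        for k in (0, 40, 120, 200):
            assert abs(cf.values[k] - exact[k]) < 3 * max(cf.stderr[k], 1e-4)

    def test_planetary_matches_classical_for_harmonic(
            self, harmonic_model, harmonic_system, harmonic_ensemble,
            harmonic_profile, harmonic_cfs):
        ens, planets = harmonic_ensemble
        std, _ = harmonic_cfs
        pl = planetary_correlation(
            harmonic_model, harmonic_system, "position", "position", ens,
            planets, DT, NSTEPS, profile=harmonic_profile)
        assert np.max(np.abs(pl.values - std.values)) < 1e-2

    def test_identity_b_side_constant(self, harmonic_model, harmonic_system,
                                      harmonic_ensemble):
        ens, planets = harmonic_ensemble
        cf = classical_wigner_correlation(
            harmonic_model, harmonic_system, "position", "identity", ens,
            planets, DT, 50)
        assert np.max(np.abs(cf.values - cf.values[0])) < 1e-12

    def test_monte_carlo_rate(self, harmonic_model, harmonic_system,
                              harmonic_ensemble):
        """Statistical error decreases as 1/sqrt(n)."""
        ens, planets = harmonic_ensemble
        q0, p0 = planets
        errs = []
        for n_c in (1000, 10_000):
            sub = ens.subset(np.arange(ens.n) < n_c)
            cf = classical_wigner_correlation(
                harmonic_model, harmonic_system, "position", "position", sub,
                (q0[:n_c], p0[:n_c]), DT, 20)
            errs.append(np.mean(cf.stderr))
        ratio = errs[0] / errs[1]
        assert 1.8 < ratio < 5.6  # sqrt(10) ~ 3.2 within block noise

    def test_empty_ensemble_rejected(self, harmonic_model, harmonic_system,
                                     harmonic_ensemble):
        ens, planets = harmonic_ensemble
        empty = ens.subset(np.zeros(ens.n, dtype=bool))
        with pytest.raises(InvalidParameterError):
            classical_wigner_correlation(
                harmonic_model, harmonic_system, "position", "position",
                empty, (planets[0][:0], planets[1][:0]), DT, 10)


class TestEnsembleConservation:
    def test_harmonic_x2_stationary_both_propagators(
            self, harmonic_model, harmonic_system, harmonic_ensemble,
            harmonic_profile):
        ens, planets = harmonic_ensemble
        for prop in ("classical", "planetary"):
            x2 = ensemble_moment_series(
                harmonic_model, harmonic_system, ens, planets, DT, 100,
                propagator=prop, profile=harmonic_profile)
            dev = np.abs(x2.values.real - x2.values.real[0])
            assert np.max(dev) < 4 * np.max(x2.stderr) + 1e-3


class TestSpectra:
    def test_pure_cosine_peaks(self):
        t = np.arange(0, 400) * 0.05
        cf = CorrelationSeries(t, np.cos(2.0 * t).astype(complex), "kubo", 0,
                               np.zeros_like(t))
        sp = spectrum_from_cf(cf, window="hann", zero_pad=4)
        w_peak = sp.omega[np.argmax(np.abs(sp.intensity))]
        assert abs(abs(w_peak) - 2.0) < 0.05
        # symmetric about zero
        mid = np.argmin(np.abs(sp.omega))
        re = sp.intensity.real
        assert np.allclose(re[mid + 1:], re[mid - 1::-1][:re.size - mid - 1],
                           atol=1e-10 * np.max(np.abs(re)))

    def test_parseval_without_window(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 256) * 0.1
        vals = rng.standard_normal(256) + 1j * rng.standard_normal(256)
        cf = CorrelationSeries(t, vals, "standard", 0, np.zeros_like(t))
        sp = spectrum_from_cf(cf, window="none")
        full = np.concatenate([np.conj(vals[:0:-1]), vals])
        lhs = np.sum(np.abs(full) ** 2) * 0.1
        dw = sp.omega[1] - sp.omega[0]
        rhs = np.sum(np.abs(sp.intensity) ** 2) * dw / (2 * math.pi)
        assert rhs == pytest.approx(lhs, rel=1e-8)

    def test_damped_cosine_lorentzian_width(self):
        gamma, w0 = 0.2, 3.0
        t = np.arange(0, 8000) * 0.02
        cf = CorrelationSeries(t, (np.exp(-gamma * t) * np.cos(w0 * t)).astype(complex),
                               "kubo", 0, np.zeros_like(t))
        sp = spectrum_from_cf(cf, window="none", zero_pad=8)
        re = sp.intensity.real
        pk = np.argmax(re)
        half = 0.5 * re[pk]
        above = np.nonzero(re > half)[0]
        grp = above[(above >= pk - 2000) & (above <= pk + 2000)]
        width = (sp.omega[grp[-1]] - sp.omega[grp[0]]) / 2
        assert width == pytest.approx(gamma, rel=0.05)

    def test_nonuniform_grid_rejected(self):
        t = np.array([0.0, 0.1, 0.3])
        cf = CorrelationSeries(t, np.ones(3, complex), "kubo", 0, np.zeros(3))
        with pytest.raises(GridError):
            spectrum_from_cf(cf)


class TestQuantumCorrectionFactor:
    def test_qh_limits_and_value(self, harmonic_system):
        qh = harmonic_qcf(np.array([0.0, 0.5, 50.0]), harmonic_system)
        assert qh.intensity[0] == pytest.approx(1.0)
        # beta*hbar*w = 1 at beta=2, w=0.5
        assert qh.intensity[1] == pytest.approx(1.0 / (1 - math.exp(-1)), rel=1e-12)
        # deep quantum asymptote QH -> beta*hbar*w
        assert qh.intensity[2] == pytest.approx(2.0 * 50.0, rel=1e-12)

    def test_spectral_ratio_recovers_qh(self, harmonic_system):
        """spectrum(standard)/spectrum(Kubo) = QH(w) at the resolved peak."""
        t = np.arange(0, 4000) * 0.05
        damp = np.exp(-0.005 * t)
        cs = CorrelationSeries(t, harmonic_position_cf(t, 1.0, harmonic_system) * damp,
                               "standard", 0, np.zeros_like(t))
        ck = CorrelationSeries(t, harmonic_kubo_position_cf(t, 1.0, harmonic_system) * damp,
                               "kubo", 0, np.zeros_like(t))
        ss = spectrum_from_cf(cs, window="none")
        sk = spectrum_from_cf(ck, window="none")
        i0 = np.argmin(np.abs(ss.omega - 1.0))
        ratio = ss.intensity[i0].real / sk.intensity[i0].real
        qh = harmonic_qcf(np.array([1.0]), harmonic_system).intensity[0]
        assert ratio == pytest.approx(qh, rel=0.01)

    def test_ratio_identity_and_floor(self):
        w = np.linspace(-2, 2, 101)
        s1 = spectrum_from_cf(
            CorrelationSeries(np.arange(64) * 0.1,
                              np.exp(-0.5 * np.arange(64) * 0.1).astype(complex),
                              "kubo", 0, np.zeros(64)), window="none")
        r = qcf_ratio(s1, s1, floor=1e-3)
        assert np.allclose(r.intensity[~r.flagged], 1.0)
        # a spectrum against a noise-floored one flags tail points
        tiny = spectrum_from_cf(
            CorrelationSeries(np.arange(64) * 0.1,
                              (np.exp(-8.0 * np.arange(64) * 0.1)
                               * np.cos(3.0 * np.arange(64) * 0.1)).astype(complex),
                              "kubo", 0, np.zeros(64)), window="none")
        r2 = qcf_ratio(s1, tiny, floor=0.5)
        assert np.any(r2.flagged)
        with pytest.raises(GridError):
            qcf_ratio(s1, harmonic_qcf(w, ThermalSystem(1.0, [1.0])))


class TestIntermediateScattering:
    def test_q_zero_gives_n_squared(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 10, size=(5, 7, 4))
        F = intermediate_scattering(pos, 10.0, 0.0)
        assert np.allclose(F.values.real, 16.0)

    def test_single_stationary_particle(self):
        pos = np.full((1, 9, 1), 3.3)
        F = intermediate_scattering(pos, 10.0, 2 * math.pi / 10)
        assert np.allclose(F.values, 1.0)

    def test_incommensurate_rejected(self):
        pos = np.zeros((1, 3, 2)) + np.array([1.0, 4.0])
        with pytest.raises(GridError, match="lattice"):
            intermediate_scattering(pos, 10.0, 0.5)

    def test_classical_ideal_gas_self_part(self):
        rng = np.random.default_rng(2)
        beta, M, L, N = 2.0, 1.0, 12.0, 4
        ntraj, nt = 6000, 25
        x0 = rng.uniform(0, L, size=(ntraj, N))
        v = rng.normal(0, math.sqrt(1 / (beta * M)), size=(ntraj, N))
        ts = 0.1 * np.arange(nt)
        pos = x0[:, None, :] + v[:, None, :] * ts[None, :, None]
        Q = 2 * math.pi * 3 / L
        F = intermediate_scattering(pos, L, Q, times=ts, part="self")
        expect = N * np.exp(-(Q**2) * ts**2 / (2 * beta * M))
        assert np.all(np.abs(F.values.real - expect)
                      <= 3 * np.maximum(F.stderr, 1e-3))

    def test_self_plus_distinct_is_total(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 10, size=(4, 6, 5))
        Q = 2 * math.pi / 10
        tot = intermediate_scattering(pos, 10.0, Q, part="total")
        slf = intermediate_scattering(pos, 10.0, Q, part="self")
        dst = intermediate_scattering(pos, 10.0, Q, part="distinct")
        assert np.allclose(slf.values + dst.values, tot.values, atol=1e-10)


class TestDiffusion:
    def test_exponential_vacf(self):
        beta, M, gamma = 2.0, 1.0, 0.5
        t = np.arange(0, 4000) * 0.01
        vac = CorrelationSeries(t, (np.exp(-gamma * t) / (beta * M)).astype(complex),
                                "kubo", 0, np.zeros_like(t))
        D, err = diffusion_from_vacf(vac, 1)
        assert D == pytest.approx(1.0 / (beta * M * gamma), rel=0.01)

    def test_bound_motion_gives_zero(self):
        """Undamped oscillatory VACF (bound motion): D = 0 within the
        plateau-spread error, and the undecayed tail is diagnosed."""
        t = np.arange(0, 6000) * 0.01
        vac = CorrelationSeries(t, np.cos(t).astype(complex), "kubo", 0,
                                np.zeros_like(t))
        with pytest.warns(UserWarning, match="not decayed"):
            D, err = diffusion_from_vacf(vac, 1)
        assert abs(D) <= 2 * err
        assert err < 1.0

    def test_warns_on_undecayed_tail(self):
        t = np.arange(0, 200) * 0.01
        vac = CorrelationSeries(t, np.ones_like(t).astype(complex), "kubo", 0,
                                np.zeros_like(t))
        with pytest.warns(UserWarning, match="not decayed"):
            diffusion_from_vacf(vac, 1)

    def test_against_msd_slope(self):
        """Green-Kubo D agrees with the mean-square-displacement slope for an
        Ornstein-Uhlenbeck velocity process."""
        rng = np.random.default_rng(4)
        kT_m, gamma, dt = 0.5, 1.0, 0.05
        nt, ntraj = 4000, 400
        a = math.exp(-gamma * dt)
        v = np.empty((ntraj, nt))
        v[:, 0] = rng.normal(0, math.sqrt(kT_m), ntraj)
        noise = rng.standard_normal((ntraj, nt - 1))
        for k in range(1, nt):
            v[:, k] = a * v[:, k - 1] + math.sqrt(kT_m * (1 - a * a)) * noise[:, k - 1]
        # VACF from the exact OU form; D from Green-Kubo
        t = dt * np.arange(2000)
        vac = CorrelationSeries(t, (kT_m * np.exp(-gamma * t)).astype(complex),
                                "kubo", 0, np.zeros_like(t))
        D_gk, _ = diffusion_from_vacf(vac, 1)
        x = np.cumsum(v, axis=1) * dt
        lag = nt // 2
        msd = np.mean((x[:, lag:] - x[:, :-lag].take([0], axis=1)) ** 2, axis=0)
        tt = dt * np.arange(lag, nt)
        slope = np.polyfit(tt[lag // 2:], msd[lag // 2:], 1)[0]
        D_msd = slope / 2
        se = D_msd * math.sqrt(2.0 / ntraj) * 3
        assert abs(D_gk - D_msd) < max(3 * se, 0.1 * D_gk)


class TestRadialDistribution:
    def test_two_clamped_particles_single_bin(self):
        cfg = np.tile([0.0, 3.0], (20, 1))
        r, g = radial_distribution(cfg, 25, 10.0)
        assert np.count_nonzero(g) == 1
        assert r[np.argmax(g)] == pytest.approx(3.0, abs=0.25)

    def test_ideal_gas_flat_and_sum_rule(self):
        rng = np.random.default_rng(5)
        N, L = 16, 18.0
        cfg = rng.uniform(0, L, size=(10_000, N))
        r, g = radial_distribution(cfg, 30, L)
        dr = r[1] - r[0]
        assert np.sum((N / L) * g * 2 * dr) == pytest.approx(N - 1, rel=0.01)
        assert np.max(np.abs(g - (N - 1) / N)) < 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            radial_distribution(np.empty((0, 4)), 10, 5.0)
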