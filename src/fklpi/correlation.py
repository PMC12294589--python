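"""Correlation functions, spectra, quantum correction factors and transport.

All ensemble averages are ratios of Monte Carlo sums over the sampled
Wigner ensemble -- the partition function cancels and is never computed.
Error bars come from block averaging over independent centroid chains.

Time grid convention: t_k = k*dt, k = 0..nsteps.  Spectra use the two-sided
extension C(-t) = C*(t) and the Fourier kernel exp(+i w t), under which the
standard/Kubo harmonic spectra are related pointwise by the harmonic
quantum correction factor QH(w) = beta*hbar*w / (1 - exp(-beta*hbar*w)).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .dynamics import classical_ensemble, planetary_ensemble
from .errors import EstimatorError, GridError, InvalidParameterError
from .fk_core import FKProfile, ThermalSystem
from .potentials import PotentialModel
from .wigner_sampling import CentroidEnsemble, Estimator, operator_estimator

__all__ = [
    "CorrelationSeries",
    "Spectrum",
    "classical_wigner_correlation",
    "planetary_correlation",
    "kubo_correlation",
    "spectrum_from_cf",
    "harmonic_qcf",
    "qcf_ratio",
    "intermediate_scattering",
    "diffusion_from_vacf",
    "radial_distribution",
]


@dataclasses.dataclass
class CorrelationSeries:
    """Uniform time grid, complex CF values, flavor and block-average errors."""

    times: np.ndarray
    values: np.ndarray
    kind: str  # "standard" | "kubo"
    n_samples: int
    stderr: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclasses.dataclass
class Spectrum:
    """Frequency grid + intensity; ``flagged`` marks floored ratio points."""

    omega: np.ndarray
    intensity: np.ndarray
    window: str = "none"
    flagged: np.ndarray | None = None


def _bare_symbol(kind: str, q, p, mass: float):
    """B-side bare Wigner symbol: position->q_t, momentum->p_t, etc."""
    if kind == "position":
        return q
    if kind == "momentum":
        return p
    if kind == "velocity":
        return p / mass
    if kind == "identity":
        return np.ones_like(q)
    raise EstimatorError(f"unsupported B-side symbol '{kind}'")


def _block_masks(ens: CentroidEnsemble, n_blocks: int):
    chains = np.unique(ens.chain_id)
    if chains.size >= max(2, n_blocks):
        ids = ens.chain_id
        labels = chains
    else:  # fall back to contiguous index blocks
        ids = (np.arange(ens.n) * n_blocks) // ens.n
        labels = np.unique(ids)
    return [ids == c for c in labels]


def _assemble_cf(
    ens: CentroidEnsemble,
    q0: np.ndarray,
    p0: np.ndarray,
    est_A: Estimator,
    b_kind: str,
    propagate,
    dt: float,
    nsteps: int,
    n_blocks: int,
) -> CorrelationSeries:
    if ens.n == 0:
        raise InvalidParameterError("empty ensemble")
    mass = ens.system.mass
    A = est_A(q0, p0, ens)  # (n_c, n_p) complex
    masks = _block_masks(ens, n_blocks)
    nb = len(masks)
    counts = np.array([int(np.sum(m)) * q0.shape[1] for m in masks])
    block_sum = np.zeros((nb, nsteps + 1), dtype=complex)

    def callback(k, q, p, *rest):
        B = _bare_symbol(b_kind, q, p, mass)
        prod = A * B
        for b, m in enumerate(masks):
            block_sum[b, k] = prod[m].sum()

    propagate(callback)
    total = block_sum.sum(axis=0) / counts.sum()
    means = block_sum / counts[:, None]
    var_re = np.var(means.real, axis=0, ddof=1)
    var_im = np.var(means.imag, axis=0, ddof=1)
    stderr = np.sqrt((var_re + var_im) / nb)
    kind = "kubo" if est_A.flavor == "kubo" else "standard"
    return CorrelationSeries(
        times=dt * np.arange(nsteps + 1), values=total, kind=kind,
        n_samples=int(counts.sum()), stderr=stderr,
    )


def classical_wigner_correlation(
    model: PotentialModel,
    system: ThermalSystem,
    estimator_A: Estimator | str,
    estimator_B: str,
    ensemble: CentroidEnsemble,
    planets: tuple[np.ndarray, np.ndarray],
    dt: float,
    nsteps: int,
    n_blocks: int = 10,
) -> CorrelationSeries:
    """Standard FK-LPI correlation function.

    CF(t) = < A_est(q,p; centroid) * B_W(q_t, p_t) > with the planets evolved
    by ordinary classical dynamics on the bare potential; the Moyal-product
    structure lives entirely on the A side, the B side is the bare Wigner
    symbol of B evaluated along the trajectory.
    """
    if isinstance(estimator_A, str):
        estimator_A = operator_estimator(estimator_A, "standard")
    q0, p0 = planets
    if q0.ndim != 2:
        raise InvalidParameterError("planets must have shape (n_centroids, n_planets)")

    def propagate(callback):
        def cb(k, q, p):
            callback(k, q, p)
        classical_ensemble(model, q0, p0, system.mass, dt, nsteps, callback=cb)

    return _assemble_cf(ensemble, q0, p0, estimator_A, estimator_B,
                        propagate, dt, nsteps, n_blocks)


def planetary_correlation(
    model: PotentialModel,
    system: ThermalSystem,
    estimator_A: Estimator | str,
    estimator_B: str,
    ensemble: CentroidEnsemble,
    planets: tuple[np.ndarray, np.ndarray],
    dt: float,
    nsteps: int,
    profile: FKProfile | None = None,
    n_blocks: int = 10,
    barrier_policy: str = "error",
) -> CorrelationSeries:
    """Ensemble-conserving planetary correlation function (1D).

    Same estimator contract as :func:`classical_wigner_correlation`, but the
    planets orbit centroids that move on W1, and physical coordinates are
    recovered from the dimensionless plane at every step.
    """
    if isinstance(estimator_A, str):
        estimator_A = operator_estimator(estimator_A, "standard")
    q0, p0 = planets
    if profile is None:
        lo = float(ensemble.xc.min())
        hi = float(ensemble.xc.max())
        pad = 0.5 * (hi - lo) + 1.0
        profile = FKProfile(model, system, lo - pad, hi + pad)

    def propagate(callback):
        planetary_ensemble(
            profile, system, ensemble.xc, ensemble.pc, q0, p0, dt, nsteps,
            callback=callback, barrier_policy=barrier_policy,
        )

    return _assemble_cf(ensemble, q0, p0, estimator_A, estimator_B,
                        propagate, dt, nsteps, n_blocks)


def kubo_correlation(
    model: PotentialModel,
    system: ThermalSystem,
    kind: str,
    ensemble: CentroidEnsemble,
    planets: tuple[np.ndarray, np.ndarray],
    dt: float,
    nsteps: int,
    propagator: str = "classical",
    profile: FKProfile | None = None,
    n_blocks: int = 10,
) -> CorrelationSeries:
    """Kubo-transformed CF: the A-side estimator is the centroid variable."""
    est = operator_estimator(kind, "kubo")
    if propagator == "classical":
        return classical_wigner_correlation(
            model, system, est, kind, ensemble, planets, dt, nsteps, n_blocks)
    if propagator == "planetary":
        return planetary_correlation(
            model, system, est, kind, ensemble, planets, dt, nsteps,
            profile=profile, n_blocks=n_blocks)
    raise InvalidParameterError(f"unknown propagator '{propagator}'")


def ensemble_moment_series(
    model: PotentialModel,
    system: ThermalSystem,
    ensemble: CentroidEnsemble,
    planets: tuple[np.ndarray, np.ndarray],
    dt: float,
    nsteps: int,
    propagator: str = "classical",
    profile: FKProfile | None = None,
    moment=lambda q, p: q**2,
    n_blocks: int = 10,
    barrier_policy: str = "error",
) -> CorrelationSeries:
    """Time series of an ensemble-averaged phase-space moment, e.g. <x^2>(t).

    The stationarity of <x^2>(t) under planetary propagation (and its drift
    under ordinary classical propagation) is the ensemble-conservation
    diagnostic of the planetary model.
    """
    q0, p0 = planets
    masks = _block_masks(ensemble, n_blocks)
    nb = len(masks)
    counts = np.array([int(np.sum(m)) * q0.shape[1] for m in masks])
    block_sum = np.zeros((nb, nsteps + 1))

    def cb(k, q, p, *rest):
        vals = moment(q, p)
        for b, m in enumerate(masks):
            block_sum[b, k] = vals[m].sum()

    if propagator == "classical":
        classical_ensemble(model, q0, p0, system.mass, dt, nsteps,
                           callback=lambda k, q, p: cb(k, q, p))
    elif propagator == "planetary":
        if profile is None:
            lo, hi = float(ensemble.xc.min()), float(ensemble.xc.max())
            pad = 0.5 * (hi - lo) + 1.0
            profile = FKProfile(model, system, lo - pad, hi + pad)
        planetary_ensemble(profile, system, ensemble.xc, ensemble.pc,
                           q0, p0, dt, nsteps, callback=cb,
                           barrier_policy=barrier_policy)
    else:
        raise InvalidParameterError(f"unknown propagator '{propagator}'")
    total = block_sum.sum(axis=0) / counts.sum()
    means = block_sum / counts[:, None]
    stderr = np.sqrt(np.var(means, axis=0, ddof=1) / nb)
    return CorrelationSeries(times=dt * np.arange(nsteps + 1),
                             values=total.astype(complex), kind="standard",
                             n_samples=int(counts.sum()), stderr=stderr)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def spectrum_from_cf(cf: CorrelationSeries, window: str = "hann",
                     zero_pad: int = 1) -> Spectrum:
    """Discrete Fourier transform of a CF with the two-sided extension.

    C(-t) = C*(t) (a no-op for real Kubo CFs); intensity
    I(w) = dt * sum_j C(t_j) exp(+i w t_j) over the symmetric grid, so a
    pure cosine gives symmetric peaks at +-w0.  ``zero_pad`` multiplies the
    number of grid points (frequency interpolation only).
    """
    t = cf.times
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-10, atol=0):
        raise GridError("CF time grid must be uniform")
    dt = float(dts[0])
    c = cf.values
    full = np.concatenate([np.conj(c[:0:-1]), c])  # t: -T..T
    n0 = full.size
    if window == "hann":
        full = full * np.hanning(n0)
    elif window != "none":
        raise InvalidParameterError(f"unknown window '{window}'")
    n = n0 * max(1, int(zero_pad))
    padded = np.zeros(n, dtype=complex)
    padded[:n0] = full
    t0 = -t[-1]
    omega = 2.0 * np.pi * np.fft.fftfreq(n, d=dt)
    F = dt * np.exp(1j * omega * t0) * n * np.fft.ifft(padded)
    order = np.argsort(omega)
    return Spectrum(omega=omega[order], intensity=F[order], window=window)


def harmonic_qcf(omega, system: ThermalSystem) -> Spectrum:
    """Harmonic quantum correction factor QH(w) = beta*hbar*w/(1-exp(-beta*hbar*w)).

    QH(0) = 1 by continuity; QH -> beta*hbar*w for beta*hbar*w >> 1.
    """
    omega = np.asarray(omega, dtype=float)
    x = system.beta * system.hbar * omega
    out = np.empty_like(x)
    small = np.abs(x) < 1e-8
    out[small] = 1.0 + 0.5 * x[small]
    xs = x[~small]
    out[~small] = xs / (1.0 - np.exp(-xs))
    return Spectrum(omega=omega, intensity=out, window="none")


def qcf_ratio(quantum_spec: Spectrum, classical_spec: Spectrum,
              floor: float = 1e-3) -> Spectrum:
    """Pointwise quantum/classical spectral ratio with a noise floor.

    Denominator magnitudes below floor*max|classical| are floored and the
    corresponding indices flagged.
    """
    if quantum_spec.omega.shape != classical_spec.omega.shape or not np.allclose(
            quantum_spec.omega, classical_spec.omega):
        raise GridError("spectra must share a common frequency grid")
    den = np.asarray(classical_spec.intensity)
    lim = floor * np.max(np.abs(den))
    flagged = np.abs(den) < lim
    den_f = np.where(flagged, np.where(np.abs(den) == 0, lim, np.sign(den.real + (den.real == 0)) * lim), den)
    ratio = np.asarray(quantum_spec.intensity) / den_f
    return Spectrum(omega=quantum_spec.omega, intensity=ratio,
                    window=quantum_spec.window, flagged=flagged)


# ---------------------------------------------------------------------------
# liquids: scattering, transport, structure
# ---------------------------------------------------------------------------

def intermediate_scattering(
    positions: np.ndarray,
    box_length: float,
    Q: float,
    times: np.ndarray | None = None,
    part: str = "total",
) -> CorrelationSeries:
    """Intermediate scattering function of a periodic 1D liquid.

    F(Q,t) = < sum_{j,j'} exp(-i Q r_j(0)) exp(+i Q r_j'(t)) > over an
    ensemble of trajectories with positions of shape (n_traj, nt, N).
    Q must be commensurate with the box (Q = 2 pi n / L); the self part
    (j = j') and distinct part are available separately.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 3:
        raise InvalidParameterError("positions must have shape (n_traj, nt, N)")
    nQ = Q * box_length / (2.0 * np.pi)
    if abs(nQ - round(nQ)) > 1e-8:
        raise GridError(
            f"Q={Q:.6g} incommensurate with the box; allowed lattice Q = 2*pi*n/L "
            f"= n*{2*np.pi/box_length:.6g}"
        )
    n_traj, nt, N = positions.shape
    phase0 = np.exp(-1j * Q * positions[:, 0, :])  # (n_traj, N)
    phaset = np.exp(1j * Q * positions)  # (n_traj, nt, N)
    if part == "self":
        F = np.mean(np.sum(phase0[:, None, :] * phaset, axis=2), axis=0)
    elif part == "total":
        rho0 = phase0.sum(axis=1)  # (n_traj,)
        rhot = phaset.sum(axis=2)  # (n_traj, nt)
        F = np.mean(rho0[:, None] * rhot, axis=0)
    elif part == "distinct":
        rho0 = phase0.sum(axis=1)
        rhot = phaset.sum(axis=2)
        F = np.mean(rho0[:, None] * rhot
                    - np.sum(phase0[:, None, :] * phaset, axis=2), axis=0)
    else:
        raise InvalidParameterError("part must be total | self | distinct")
    blocks = np.array_split(np.arange(n_traj), min(10, n_traj))
    if part == "self":
        per = np.sum(phase0[:, None, :] * phaset, axis=2)
    else:
        per = (phase0.sum(axis=1))[:, None] * phaset.sum(axis=2)
    bm = np.array([per[b].mean(axis=0) for b in blocks])
    stderr = np.sqrt((np.var(bm.real, axis=0, ddof=1)
                      + np.var(bm.imag, axis=0, ddof=1)) / len(blocks))
    t = times if times is not None else np.arange(nt, dtype=float)
    return CorrelationSeries(times=np.asarray(t, float), values=F, kind="standard",
                             n_samples=n_traj, stderr=stderr)


def diffusion_from_vacf(vacf: CorrelationSeries, dimension: int = 1,
                        tail_fraction: float = 0.25) -> tuple[float, float]:
    """Green-Kubo diffusion constant D = (1/d) \\int_0^T Re vacf dt.

    Trapezoidal cumulative integral with plateau detection over the last
    ``tail_fraction`` of the window; warns when the VACF has not decayed
    into its noise band by the end of the window.
    """
    from scipy.integrate import cumulative_trapezoid

    re = vacf.values.real
    t = vacf.times
    cum = cumulative_trapezoid(re, t, initial=0.0) / dimension
    ntail = max(2, int(tail_fraction * t.size))
    tail = re[-max(2, t.size // 10):]
    noise = np.mean(vacf.stderr[-max(2, t.size // 10):]) if np.any(vacf.stderr) else 0.0
    scale = np.max(np.abs(re)) if np.max(np.abs(re)) > 0 else 1.0
    if abs(np.mean(tail)) > max(3.0 * noise, 1e-3 * scale):
        warnings.warn(
            "VACF has not decayed to noise within the window; "
            f"tail mean {np.mean(tail):.3g}, plateau diagnostics: "
            f"last-quarter D spread {np.ptp(cum[-ntail:]):.3g}",
            stacklevel=2,
        )
    D = float(np.mean(cum[-ntail:]))
    err = float(np.std(cum[-ntail:]))
    return D, err


def radial_distribution(
    configs: np.ndarray, n_bins: int, box_length: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pair distribution g(r) of a periodic 1D liquid.

    Standard finite-N normalization (ideal-gas density N/L), so the sum rule
    \\int_0^{L/2} rho g(r) * 2 dr = N - 1 holds exactly on average.
    Returns (bin centers, g).
    """
    configs = np.asarray(configs, dtype=float)
    if configs.ndim == 1:
        configs = configs[None, :]
    n_cfg, N = configs.shape
    if n_cfg == 0:
        raise InvalidParameterError("no configurations given")
    if N < 2:
        raise InvalidParameterError("need at least two particles")
    L = float(box_length)
    r_max = 0.5 * L
    iu, ju = np.triu_indices(N, k=1)
    dx = configs[:, iu] - configs[:, ju]
    dx -= L * np.round(dx / L)
    r = np.abs(dx).ravel()
    hist, edges = np.histogram(r, bins=n_bins, range=(0.0, r_max))
    dr = edges[1] - edges[0]
    centers = 0.5 * (edges[1:] + edges[:-1])
    rho = N / L
    # per config: ideal pair count in a bin = N * rho * (2 dr) / 2
    ideal = n_cfg * N * rho * dr
    g = hist / ideal
    return centers, g
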