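"""Exact 1D quantum references: grid eigensolver, spectral correlation
functions and the numerically exact Boltzmann-Wigner function.

These are validation oracles.  They live in their own namespace and nothing
in the production sampling/propagation path imports them; tests and the
acceptance checks compare FK-LPI output against them.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .correlation import CorrelationSeries
from .errors import GridError, InvalidParameterError
from .fk_core import ThermalSystem
from .potentials import PotentialModel

__all__ = [
    "SpectralSolution",
    "grid_eigensolve",
    "exact_correlation",
    "exact_wigner_boltzmann",
    "exact_wigner_operator_product",
    "harmonic_position_cf",
    "harmonic_kubo_position_cf",
    "harmonic_wigner",
]


@dataclasses.dataclass
class SpectralSolution:
    """Eigenpairs of a 1D Hamiltonian on a uniform grid.

    Wavefunctions are L2-normalized with the grid weight dx and mutually
    orthogonal to 1e-10.
    """

    grid: np.ndarray
    energies: np.ndarray
    wavefunctions: np.ndarray  # (n_states, n_points)
    mass: float
    hbar: float

    @property
    def dx(self) -> float:
        return float(self.grid[1] - self.grid[0])


def grid_eigensolve(
    model: PotentialModel,
    x_range: tuple[float, float],
    n_points: int = 800,
    n_states: int = 20,
    mass: float = 1.0,
    hbar: float = 1.0,
    boundary_tol: float = 1e-8,
    check_boundary: bool = True,
) -> SpectralSolution:
    """Diagonalize H = -hbar^2/(2m) d2/dx2 + V on a hard-wall uniform grid.

    Fourier-grid (sinc-DVR, Colbert-Miller) kinetic energy, so eigenvalues
    converge spectrally in the grid spacing; raises GridError when a
    requested state has boundary amplitude above ``boundary_tol`` (i.e. is
    not converged inside the box).  Pass ``check_boundary=False`` for
    particle-in-a-box style problems where boundary walls are physical.
    """
    from scipy.linalg import eigh

    if n_points < 200:
        raise InvalidParameterError("n_points must be >= 200")
    lo, hi = map(float, x_range)
    x = np.linspace(lo, hi, n_points)
    dx = x[1] - x[0]
    v = np.asarray(model.v(x), dtype=float)
    # sinc-DVR kinetic matrix on the hard-wall grid
    i = np.arange(n_points)
    dij = i[:, None] - i[None, :]
    kin = hbar**2 / (2.0 * mass * dx**2)
    with np.errstate(divide="ignore"):
        T = kin * 2.0 * np.where(dij == 0, np.pi**2 / 6.0, 1.0 / dij.astype(float) ** 2)
    T *= (-1.0) ** dij
    H = T + np.diag(v)
    energies, vecs = eigh(H, subset_by_index=(0, n_states - 1))
    psi = vecs.T / math.sqrt(dx)  # (n_states, n_points), grid-normalized
    # fix sign convention: positive leading lobe
    for k in range(psi.shape[0]):
        j = np.argmax(np.abs(psi[k]) > 1e-3 * np.max(np.abs(psi[k])))
        if psi[k, j] < 0:
            psi[k] *= -1.0
    if check_boundary:
        amp = np.maximum(np.abs(psi[:, 0]), np.abs(psi[:, -1])) * math.sqrt(dx)
        if np.any(amp > boundary_tol):
            bad = int(np.argmax(amp > boundary_tol))
            raise GridError(
                f"state {bad} not converged within x_range "
                f"(boundary amplitude {amp[bad]:.2e} > {boundary_tol:g})"
            )
    return SpectralSolution(grid=x, energies=energies, wavefunctions=psi,
                            mass=mass, hbar=hbar)


def _operator_matrix(sol: SpectralSolution, op) -> np.ndarray:
    """Matrix elements of op in the eigenbasis.

    op may be 'position', 'momentum', 'identity', a callable f(x) applied
    diagonally in position, or an explicit matrix.
    """
    psi = sol.wavefunctions
    dx = sol.dx
    if isinstance(op, np.ndarray):
        return op
    if op == "identity":
        return np.eye(psi.shape[0])
    if op == "position":
        return (psi * sol.grid) @ psi.T * dx
    if callable(op):
        return (psi * op(sol.grid)) @ psi.T * dx
    if op == "momentum":
        dpsi = np.gradient(psi, dx, axis=1)
        M = -1j * sol.hbar * (psi @ dpsi.T) * dx
        return 0.5 * (M + M.conj().T)  # enforce hermiticity of -i hbar d/dx
    raise InvalidParameterError(f"unknown operator spec {op!r}")


def _truncate(sol: SpectralSolution, beta: float, tol: float = 1e-10) -> int:
    E = sol.energies - sol.energies[0]
    keep = np.nonzero(np.exp(-beta * E) >= tol)[0]
    n_therm = int(keep[-1]) + 1
    if n_therm >= sol.energies.size:
        raise InvalidParameterError(
            "insufficient states: Boltzmann tail not truncated below tolerance"
        )
    return n_therm


def exact_correlation(
    sol: SpectralSolution,
    opA,
    opB,
    system: ThermalSystem,
    times: np.ndarray,
    kind: str = "standard",
) -> CorrelationSeries:
    """Spectral-sum quantum CF with B(t) = exp(-iHt/hbar) B exp(+iHt/hbar).

    C(t) = Z^-1 sum_{n,m} e^{-beta E_n} A_nm B_mn e^{+i(E_n-E_m)t/hbar};
    the Kubo flavor reweights each transition by
    (e^{-beta E_n} - e^{-beta E_m}) / (beta (E_m - E_n) e^{-beta E_n}).
    """
    beta, hbar = system.beta, system.hbar
    E = sol.energies
    n_therm = _truncate(sol, beta)
    A = _operator_matrix(sol, opA)
    B = _operator_matrix(sol, opB)
    w = np.exp(-beta * (E - E[0]))
    Z = np.sum(w[:n_therm])
    times = np.asarray(times, dtype=float)
    nstates = E.size
    C = np.zeros(times.size, dtype=complex)
    for n in range(n_therm):
        for m in range(nstates):
            amp = A[n, m] * B[m, n]
            if amp == 0:
                continue
            if kind == "standard":
                wt = w[n]
            elif kind == "kubo":
                dE = E[m] - E[n]
                if abs(dE) < 1e-12:
                    wt = w[n]
                else:
                    wt = (w[n] - w[m]) / (beta * dE)
            else:
                raise InvalidParameterError("kind must be standard | kubo")
            C += wt * amp * np.exp(1j * (E[n] - E[m]) * times / hbar)
    C /= Z
    return CorrelationSeries(times=times, values=C, kind=kind,
                             n_samples=0, stderr=np.zeros(times.size))


def exact_wigner_boltzmann(
    sol: SpectralSolution,
    system: ThermalSystem,
    x_grid: np.ndarray,
    p_grid: np.ndarray,
    n_eta: int = 801,
    alias_check: bool = True,
) -> np.ndarray:
    """Numerically exact (unnormalized) Boltzmann-Wigner function on a grid.

    W(x,p) = int d_eta exp(-i p eta / hbar) <x+eta/2| e^{-beta H} |x-eta/2>
    with the density matrix built from the spectral solution and the eta
    integral done by trapezoid on interpolated wavefunctions.  Raises on
    aliasing: values must be stable to 1e-6 under eta-grid doubling.
    """
    from scipy.interpolate import CubicSpline

    beta, hbar = system.beta, system.hbar
    n_therm = _truncate(sol, beta)
    w = np.exp(-beta * (sol.energies[:n_therm] - sol.energies[0]))
    splines = [CubicSpline(sol.grid, sol.wavefunctions[k], extrapolate=False)
               for k in range(n_therm)]
    span = sol.grid[-1] - sol.grid[0]

    def evaluate(n_eta_pts: int) -> np.ndarray:
        eta = np.linspace(-span, span, n_eta_pts)
        out = np.zeros((x_grid.size, p_grid.size))
        phase = np.exp(-1j * np.outer(eta, p_grid) / hbar)  # (eta, p)
        for i, xv in enumerate(x_grid):
            xp = xv + 0.5 * eta
            xm = xv - 0.5 * eta
            rho = np.zeros(eta.size)
            for k in range(n_therm):
                a = splines[k](xp)
                b = splines[k](xm)
                a = np.nan_to_num(a)
                b = np.nan_to_num(b)
                rho += w[k] * a * b
            out[i] = np.trapezoid(rho[:, None] * phase, eta, axis=0).real
        return out

    W = evaluate(n_eta)
    if alias_check:
        W2 = evaluate(2 * n_eta - 1)
        scale = np.max(np.abs(W2))
        if np.max(np.abs(W2 - W)) > 1e-6 * scale:
            raise GridError("aliasing detected in Wigner eta-integration "
                            "(value drift > 1e-6 under grid doubling)")
        W = W2
    return W


def exact_wigner_operator_product(
    sol: SpectralSolution,
    system: ThermalSystem,
    x_grid: np.ndarray,
    p_grid: np.ndarray,
    n_eta: int = 801,
) -> np.ndarray:
    """Numeric Wigner transform of the operator product e^{-beta H} x_hat.

    Same eta-integration as :func:`exact_wigner_boltzmann` with the position
    operator acting on the right (multiplication by x - eta/2).  Complex
    valued; the ratio against the Boltzmann-Wigner function is the oracle
    that pins the Moyal-product estimator signs.
    """
    from scipy.interpolate import CubicSpline

    beta, hbar = system.beta, system.hbar
    n_therm = _truncate(sol, beta)
    w = np.exp(-beta * (sol.energies[:n_therm] - sol.energies[0]))
    splines = [CubicSpline(sol.grid, sol.wavefunctions[k], extrapolate=False)
               for k in range(n_therm)]
    span = sol.grid[-1] - sol.grid[0]
    eta = np.linspace(-span, span, n_eta)
    phase = np.exp(-1j * np.outer(eta, p_grid) / hbar)
    out = np.zeros((x_grid.size, p_grid.size), dtype=complex)
    for i, xv in enumerate(x_grid):
        xp = xv + 0.5 * eta
        xm = xv - 0.5 * eta
        rho = np.zeros(eta.size)
        for k in range(n_therm):
            a = np.nan_to_num(splines[k](xp))
            b = np.nan_to_num(splines[k](xm))
            rho += w[k] * a * b
        out[i] = np.trapezoid((rho * xm)[:, None] * phase, eta, axis=0)
    return out


# ---------------------------------------------------------------------------
# closed harmonic forms
# ---------------------------------------------------------------------------

def harmonic_position_cf(times, omega: float, system: ThermalSystem) -> np.ndarray:
    """(hbar/2Mw)[coth(beta hbar w/2) cos wt - i sin wt] (B(t)=e^{-iHt}B e^{iHt})."""
    t = np.asarray(times, dtype=float)
    M, hbar, beta = system.mass, system.hbar, system.beta
    pref = hbar / (2.0 * M * omega)
    return pref * (1.0 / np.tanh(0.5 * beta * hbar * omega) * np.cos(omega * t)
                   - 1j * np.sin(omega * t))


def harmonic_kubo_position_cf(times, omega: float, system: ThermalSystem) -> np.ndarray:
    """Kubo-transformed harmonic position CF, (1/(beta M w^2)) cos wt."""
    t = np.asarray(times, dtype=float)
    return np.cos(omega * t) / (system.beta * system.mass * omega**2)


def harmonic_wigner(x_grid, p_grid, omega: float, system: ThermalSystem) -> np.ndarray:
    """Exact harmonic Boltzmann-Wigner function (unnormalized) on a grid."""
    M, hbar, beta = system.mass, system.hbar, system.beta
    th = math.tanh(0.5 * beta * hbar * omega)
    X, P = np.meshgrid(np.asarray(x_grid, float), np.asarray(p_grid, float),
                       indexing="ij")
    H = P**2 / (2 * M) + 0.5 * M * omega**2 * X**2
    return np.exp(-2.0 * th / (hbar * omega) * H)
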