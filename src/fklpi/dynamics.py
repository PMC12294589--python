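"""Propagators: classical velocity Verlet and planetary dynamics.

Standard FK-LPI propagates the sampled planets with ordinary classical
dynamics on the bare potential.  The ensemble-conserving planetary variant
moves the centroid classically on the centroid potential W1 while the planet
rotates around it at the local effective frequency in dimensionless
coordinates:

    q~ = sqrt(M Omega / hbar alpha) (q - xc),   p~ = (p - pc)/sqrt(hbar alpha M Omega),
    dq~/dt =  Omega(xc(t)) p~,   dp~/dt = -Omega(xc(t)) q~.

Each substep applies the exact 2x2 rotation through Omega(xc_mid)*dt with
the frequency frozen at the substep midpoint centroid position, so the
planet radius q~^2 + p~^2 is conserved to machine precision.  Physical
coordinates are recovered with Omega and alpha evaluated at the
instantaneous centroid position.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .errors import FKLPIError, InvalidParameterError
from .fk_core import FKProfile, ThermalSystem
from .potentials import PairLiquidLJ, PotentialModel

__all__ = [
    "Trajectory",
    "PlanetState",
    "classical_trajectory",
    "classical_ensemble",
    "centroid_force",
    "planetary_trajectory",
    "planetary_ensemble",
]


@dataclasses.dataclass
class Trajectory:
    """Time grid plus phase-space history (uniform step)."""

    times: np.ndarray
    positions: np.ndarray  # (nt, d) or (nt, ...) for ensembles
    momenta: np.ndarray
    energy: np.ndarray | None = None

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclasses.dataclass
class PlanetState:
    """Planet + centroid state at one instant."""

    q_tilde: np.ndarray
    p_tilde: np.ndarray
    centroid_x: np.ndarray
    centroid_p: np.ndarray
    time: float


@dataclasses.dataclass
class PlanetaryTrajectory:
    """History of a planetary run: centroid, dimensionless and physical planes."""

    times: np.ndarray
    centroid_x: np.ndarray
    centroid_p: np.ndarray
    q_tilde: np.ndarray
    p_tilde: np.ndarray
    positions: np.ndarray  # physical planet coordinates q_t
    momenta: np.ndarray    # physical planet momenta p_t
    energy: np.ndarray | None = None  # centroid energy pc^2/2M + W1(xc)


def _forces_of(model: PotentialModel):
    """Batched force function for 1D element-wise or pair-liquid models."""
    if isinstance(model, PairLiquidLJ):
        return model.forces_batch
    def f(x):
        return -np.asarray(model.dv(x))
    return f


def _max_frequency(model: PotentialModel, x0: np.ndarray, masses) -> float:
    try:
        H = model.hessian(x0)
        lam = np.linalg.eigvalsh(H / np.sqrt(np.outer(masses, masses)))
        return float(np.sqrt(np.max(np.abs(lam))))
    except Exception:
        return 0.0


def classical_trajectory(
    model: PotentialModel,
    start,
    dt: float,
    nsteps: int,
    system: ThermalSystem | None = None,
    masses=None,
) -> Trajectory:
    """Velocity-Verlet integration of one phase point on the bare potential.

    ``start`` is anything with .q/.p attributes, a (q, p) tuple, or a pair of
    vectors.  Warns when dt*omega_max > 0.1.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    if hasattr(start, "q"):
        q0, p0 = start.q, start.p
    else:
        q0, p0 = start
    q = np.atleast_1d(np.asarray(q0, float)).copy()
    p = np.atleast_1d(np.asarray(p0, float)).copy()
    if masses is None:
        masses = system.masses if system is not None else np.ones_like(q)
    m = np.broadcast_to(np.asarray(masses, float), q.shape)

    wmax = _max_frequency(model, q, m)
    if wmax * dt > 0.1:
        warnings.warn(
            f"dt*omega_max = {wmax*dt:.3g} > 0.1; integration may be inaccurate",
            stacklevel=2,
        )

    qs = np.empty((nsteps + 1,) + q.shape)
    ps = np.empty_like(qs)
    es = np.empty(nsteps + 1)
    g = np.asarray(model.gradient(q), float)
    qs[0], ps[0] = q, p
    es[0] = model.value(q) + float(np.sum(p**2 / (2 * m)))
    for k in range(1, nsteps + 1):
        p = p - 0.5 * dt * g
        q = q + dt * p / m
        g = np.asarray(model.gradient(q), float)
        if not np.all(np.isfinite(g)):
            raise FKLPIError(f"non-finite force at step {k}")
        p = p - 0.5 * dt * g
        qs[k], ps[k] = q, p
        es[k] = model.value(q) + float(np.sum(p**2 / (2 * m)))
    times = dt * np.arange(nsteps + 1)
    return Trajectory(times=times, positions=qs, momenta=ps, energy=es)


def classical_ensemble(
    model: PotentialModel,
    q0: np.ndarray,
    p0: np.ndarray,
    mass: float | np.ndarray,
    dt: float,
    nsteps: int,
    callback=None,
):
    """Vectorized velocity Verlet for a whole ensemble.

    ``q0``/``p0`` have shape (n,) for 1D models or (n, N) for pair liquids.
    When ``callback(k, q, p)`` is given, nothing is stored and the callback
    is invoked at every step (k = 0 .. nsteps) -- the correlation drivers
    use this to accumulate on the fly.  Otherwise full (nsteps+1, ...)
    arrays are returned.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    forces = _forces_of(model)
    q = np.array(q0, dtype=float)
    p = np.array(p0, dtype=float)
    m = mass
    f = forces(q)
    store = callback is None
    if store:
        qs = np.empty((nsteps + 1,) + q.shape)
        ps = np.empty_like(qs)
        qs[0], ps[0] = q, p
    else:
        callback(0, q, p)
    for k in range(1, nsteps + 1):
        p = p + 0.5 * dt * f
        q = q + dt * p / m
        f = forces(q)
        p = p + 0.5 * dt * f
        if store:
            qs[k], ps[k] = q, p
        else:
            callback(k, q, p)
    if store:
        return qs, ps
    return None


def centroid_force(
    profile_or_model,
    xc,
    system: ThermalSystem | None = None,
    fd_step: float = 1e-4,
):
    """Force on the centroid, -dW1/dxc.

    For 1D, pass an :class:`FKProfile`; the force is the derivative of its
    cubic-spline W1 cache (the grid extends transparently when xc leaves
    it).  For multi-D, pass the model and a system: central differences of
    W1 with per-call effective-frequency solves (expensive; intended for
    small systems).
    """
    if isinstance(profile_or_model, FKProfile):
        return -profile_or_model.dW1(xc)
    from .fk_core import effective_frequency_matrix

    model = profile_or_model
    if system is None:
        raise InvalidParameterError("multi-D centroid_force needs a ThermalSystem")
    xc = np.asarray(xc, float)
    g = np.empty_like(xc)
    for i in range(xc.size):
        xp, xm = xc.copy(), xc.copy()
        xp[i] += fd_step
        xm[i] -= fd_step
        Wp = effective_frequency_matrix(model, xp, system, rng=0).W1
        Wm = effective_frequency_matrix(model, xm, system, rng=0).W1
        g[i] = (Wp - Wm) / (2 * fd_step)
    return -g


def _planet_step(profile, system, xc, pc, qt_, pt_, dt, barrier_policy, omega_min):
    """One velocity-Verlet + rotation substep; vectorized over an ensemble."""
    M = system.mass
    f = -profile.dW1(xc)
    pc_half = pc + 0.5 * dt * f
    xc_new = xc + dt * pc_half / M
    xc_mid = 0.5 * (xc + xc_new)
    om2 = profile.omega2(xc_mid)
    om2 = np.asarray(om2, dtype=float)
    bad = om2 <= 0
    if np.any(bad):
        if barrier_policy == "error":
            raise FKLPIError(
                "planetary centroid entered a barrier region (Omega^2 <= 0)"
            )
        om2 = np.where(bad, omega_min**2, om2)
    om = np.sqrt(om2)
    th = om * dt
    c, s = np.cos(th), np.sin(th)
    if qt_.ndim == 2 and c.ndim == 1:  # shared centroid row per planet column
        c, s = c[:, None], s[:, None]
    qt_new = c * qt_ + s * pt_
    pt_new = -s * qt_ + c * pt_
    f_new = -profile.dW1(xc_new)
    pc_new = pc_half + 0.5 * dt * f_new
    return xc_new, pc_new, qt_new, pt_new


def _physical(profile, system, xc, qt_, pt_, pc, clamp=False):
    """Back-transform to physical coordinates with Omega, alpha evaluated at
    the instantaneous centroid.  With the 'clamp' barrier policy a negative
    momentum-width is floored so the recovery stays finite."""
    vq = np.asarray(profile.var_q(xc), dtype=float)
    vp = np.asarray(profile.var_p(xc), dtype=float)
    if clamp:
        vp = np.maximum(vp, 1e-12)
    q = xc + np.sqrt(2.0 * vq) * qt_
    p = pc + np.sqrt(2.0 * vp) * pt_
    return q, p


def planetary_trajectory(
    model: PotentialModel,
    c0,
    planet0,
    dt: float,
    nsteps: int,
    system: ThermalSystem,
    profile: FKProfile | None = None,
    barrier_policy: str = "error",
    omega_min: float = 1e-6,
) -> PlanetaryTrajectory:
    """Planetary propagation of one planet around one centroid (1D).

    The centroid moves by velocity Verlet on W1; the dimensionless planet is
    rotated exactly through Omega(xc_mid)*dt each step.  ``barrier_policy``
    selects what happens if the centroid wanders into Omega^2 <= 0 territory:
    'error' raises, 'clamp' substitutes omega_min.
    """
    if profile is None:
        x0 = float(np.atleast_1d(c0.xc)[0])
        span = max(2.0, 4.0 * abs(x0))
        profile = FKProfile(model, system, x0 - span, x0 + span)
    xc = np.atleast_1d(np.asarray(c0.xc, float))[:1].copy()
    pc = np.atleast_1d(np.asarray(c0.pc, float))[:1].copy()
    q = np.atleast_1d(np.asarray(planet0.q, float))[:1]
    p = np.atleast_1d(np.asarray(planet0.p, float))[:1]
    vq0 = np.asarray(profile.var_q(xc), float)
    vp0 = np.asarray(profile.var_p(xc), float)
    qt_ = (q - xc) / np.sqrt(2.0 * vq0)
    pt_ = (p - pc) / np.sqrt(2.0 * vp0)

    M = system.mass
    nt = nsteps + 1
    out = PlanetaryTrajectory(
        times=dt * np.arange(nt),
        centroid_x=np.empty((nt, 1)), centroid_p=np.empty((nt, 1)),
        q_tilde=np.empty((nt, 1)), p_tilde=np.empty((nt, 1)),
        positions=np.empty((nt, 1)), momenta=np.empty((nt, 1)),
        energy=np.empty(nt),
    )

    clamp = barrier_policy == "clamp"

    def record(k, xc, pc, qt_, pt_):
        out.centroid_x[k], out.centroid_p[k] = xc, pc
        out.q_tilde[k], out.p_tilde[k] = qt_, pt_
        qphys, pphys = _physical(profile, system, xc, qt_, pt_, pc, clamp=clamp)
        out.positions[k], out.momenta[k] = qphys, pphys
        out.energy[k] = float(pc[0] ** 2 / (2 * M) + profile.W1(float(xc[0])))

    record(0, xc, pc, qt_, pt_)
    for k in range(1, nt):
        xc, pc, qt_, pt_ = _planet_step(
            profile, system, xc, pc, qt_, pt_, dt, barrier_policy, omega_min
        )
        record(k, xc, pc, qt_, pt_)
    return out


def planetary_ensemble(
    profile: FKProfile,
    system: ThermalSystem,
    xc0: np.ndarray,
    pc0: np.ndarray,
    q0: np.ndarray,
    p0: np.ndarray,
    dt: float,
    nsteps: int,
    callback=None,
    barrier_policy: str = "error",
    omega_min: float = 1e-6,
):
    """Vectorized planetary propagation (1D).

    ``xc0``/``pc0`` have shape (n,); ``q0``/``p0`` are physical planet
    coordinates of shape (n,) or (n, n_planets) sharing the centroid rows.
    ``callback(k, q, p, xc, pc)`` receives physical coordinates at every
    step; without it, full histories of (q, p) are returned.
    """
    xc = np.array(xc0, dtype=float)
    pc = np.array(pc0, dtype=float)
    q = np.array(q0, dtype=float)
    p = np.array(p0, dtype=float)
    per_planet = q.ndim == 2

    clamp = barrier_policy == "clamp"

    def widths(xc_arr):
        vq = np.asarray(profile.var_q(xc_arr), dtype=float)
        vp = np.asarray(profile.var_p(xc_arr), dtype=float)
        if clamp:
            vp = np.maximum(vp, 1e-12)
        if per_planet:
            return vq[:, None], vp[:, None]
        return vq, vp

    vq0, vp0 = widths(xc)
    xc_b = xc[:, None] if per_planet else xc
    pc_b = pc[:, None] if per_planet else pc
    qt_ = (q - xc_b) / np.sqrt(2.0 * vq0)
    pt_ = (p - pc_b) / np.sqrt(2.0 * vp0)

    store = callback is None
    if store:
        qs = np.empty((nsteps + 1,) + q.shape)
        ps = np.empty_like(qs)

    def emit(k):
        vq, vp = widths(xc)
        xcb = xc[:, None] if per_planet else xc
        pcb = pc[:, None] if per_planet else pc
        qphys = xcb + np.sqrt(2.0 * vq) * qt_
        pphys = pcb + np.sqrt(2.0 * vp) * pt_
        if store:
            qs[k], ps[k] = qphys, pphys
        else:
            callback(k, qphys, pphys, xc, pc)

    emit(0)
    for k in range(1, nsteps + 1):
        xc, pc, qtn, ptn = _planet_step(
            profile, system, xc, pc,
            qt_, pt_, dt, barrier_policy, omega_min,
        )
        qt_, pt_ = qtn, ptn
        emit(k)
    if store:
        return qs, ps
    return None
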