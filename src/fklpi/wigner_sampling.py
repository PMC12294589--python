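"""Sampling the FK Boltzmann-Wigner distribution.

Two stages: a Metropolis walk over centroids (xc, pc) with weight
exp(-beta pc^2/2M - beta W1(xc)), followed by exact Gaussian sampling of the
quantum fluctuation cloud ("planets") around each centroid from the analytic
QDO Wigner transform

    (delta_FK)_W[q,p] = (2/alpha) exp( -(q-xc)^2/(2 var_q) - (p-pc)^2/(2 var_p) ),

with var_q = hbar*alpha/(2 M Omega) and var_p = M*Omega*alpha*hbar/2.  At a
barrier (Omega^2 < 0) var_p is negative and the momentum sampling is
ill-defined; integrating the centroid momentum out analytically leaves a
combined momentum Gaussian of variance M/beta + var_p, positive exactly for
hbar*|Omega|*beta < pi.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .errors import BarrierValidityError, EstimatorError, InvalidParameterError
from .fk_core import (
    EffectiveFrequencyResult,
    FKProfile,
    ThermalSystem,
    effective_frequency_matrix,
    solve_effective_frequency,
)
from .potentials import PotentialModel

logger = logging.getLogger(__name__)

__all__ = [
    "CentroidSample",
    "PhasePoint",
    "CentroidEnsemble",
    "MCMCOptions",
    "qdo_wigner_value",
    "sample_centroid_ensemble",
    "sample_qdo_fluctuations",
    "sample_fluctuation_cloud",
    "sample_mixed_cloud",
    "sample_barrier_marginal",
    "operator_estimator",
    "Estimator",
    "boltzmann_wigner_on_grid",
    "save_ensemble",
    "load_ensemble",
]


@dataclasses.dataclass
class CentroidSample:
    """One centroid phase point with its converged FK data and log weight."""

    xc: np.ndarray
    pc: np.ndarray
    eff: EffectiveFrequencyResult
    log_weight: float


@dataclasses.dataclass
class PhasePoint:
    """A fluctuation ("planet") phase point attached to a parent centroid."""

    q: np.ndarray
    p: np.ndarray
    parent: CentroidSample


class CentroidEnsemble:
    """Array-backed collection of centroid samples (duck-typed sample list).

    Fields are stacked over samples; ``__getitem__`` materializes individual
    :class:`CentroidSample` views.  1D ensembles store flat (n,) arrays.
    """

    def __init__(self, system: ThermalSystem, xc, pc, omega2, a2, alpha,
                 var_q, var_p, W1, log_weight, chain_id=None,
                 acceptance_rate=float("nan")):
        self.system = system
        self.xc = np.asarray(xc, dtype=float)
        self.pc = np.asarray(pc, dtype=float)
        self.omega2 = np.asarray(omega2, dtype=float)
        self.a2 = np.asarray(a2, dtype=float)
        self.alpha = np.asarray(alpha, dtype=float)
        self.var_q = np.asarray(var_q, dtype=float)
        self.var_p = np.asarray(var_p, dtype=float)
        self.W1 = np.asarray(W1, dtype=float)
        self.log_weight = np.asarray(log_weight, dtype=float)
        n = self.xc.shape[0]
        self.chain_id = (np.zeros(n, dtype=int) if chain_id is None
                         else np.asarray(chain_id, dtype=int))
        self.acceptance_rate = acceptance_rate

    @property
    def n(self) -> int:
        return self.xc.shape[0]

    @property
    def dimension(self) -> int:
        return 1 if self.xc.ndim == 1 else self.xc.shape[1]

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, i: int) -> CentroidSample:
        eff = EffectiveFrequencyResult(
            xc=np.atleast_1d(self.xc[i]), omega2=self.omega2[i], a2=self.a2[i],
            alpha=self.alpha[i], var_q=self.var_q[i], var_p_qdo=self.var_p[i],
            W1=float(self.W1[i]), smeared_V=math.nan, iterations=0,
            converged=True, barrier=bool(np.any(np.atleast_1d(self.omega2[i]) < 0)),
            mass=self.system.mass if self.dimension == 1 else self.system.masses,
        )
        return CentroidSample(
            xc=np.atleast_1d(self.xc[i]), pc=np.atleast_1d(self.pc[i]),
            eff=eff, log_weight=float(self.log_weight[i]),
        )

    def __iter__(self):
        return (self[i] for i in range(self.n))

    def subset(self, mask: np.ndarray) -> "CentroidEnsemble":
        """Row-masked copy (e.g. to exclude barrier centroids)."""
        return CentroidEnsemble(
            self.system, self.xc[mask], self.pc[mask], self.omega2[mask],
            self.a2[mask], self.alpha[mask], self.var_q[mask],
            self.var_p[mask], self.W1[mask], self.log_weight[mask],
            self.chain_id[mask], acceptance_rate=self.acceptance_rate,
        )


def qdo_wigner_value(q, p, c: CentroidSample) -> float:
    """Analytic QDO Wigner transform value at (q, p), product over modes.

    Per mode: (2/alpha) exp(-(q-xc)^2/(2 var_q) - (p-pc)^2/(2 var_p)).
    Requires Omega^2 > 0 on every mode; barrier modes carry var_p < 0 and
    must go through :func:`sample_barrier_marginal`.
    """
    q = np.atleast_1d(np.asarray(q, float))
    p = np.atleast_1d(np.asarray(p, float))
    eff = c.eff
    var_q = np.atleast_1d(np.asarray(eff.var_q, float))
    var_p = np.atleast_1d(np.asarray(eff.var_p_qdo, float))
    alpha = np.atleast_1d(np.asarray(eff.alpha, float))
    if np.any(~(var_p > 0)):
        raise BarrierValidityError(
            "qdo_wigner_value: barrier mode present (var_p <= 0); "
            "use sample_barrier_marginal"
        )
    expo = -np.sum((q - c.xc) ** 2 / (2 * var_q) + (p - c.pc) ** 2 / (2 * var_p))
    return float(np.prod(2.0 / alpha) * math.exp(expo))


@dataclasses.dataclass
class MCMCOptions:
    """Metropolis options; step is auto-tuned to 30-50% acceptance when None."""

    step: float | None = None
    burn_in: int = 500
    thinning: int = 5
    n_chains: int = 10
    start: np.ndarray | None = None


def _find_start(model: PotentialModel, span: float = 10.0) -> float:
    xs = np.linspace(-span, span, 801)
    try:
        vs = np.asarray(model.v(xs), dtype=float)
        return float(xs[np.argmin(vs)])
    except Exception:
        return 0.0


def sample_centroid_ensemble(
    model: PotentialModel,
    system: ThermalSystem,
    n: int,
    mcmc: MCMCOptions | None = None,
    rng_seed: int | np.random.Generator = 0,
    profile: FKProfile | None = None,
    solver_opts: dict | None = None,
) -> CentroidEnsemble:
    """Metropolis chain over centroids targeting exp(-beta pc^2/2M - beta W1).

    Momenta are drawn exactly (Gaussian, variance M/beta).  For 1D models a
    precomputed :class:`FKProfile` makes W1 evaluations cheap; without one,
    the effective frequency is solved per proposal and cached per accepted
    position.  Proposals where the solve fails are rejected and counted.
    Fixed seeds give bitwise-identical chains.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    mcmc = mcmc or MCMCOptions()
    rng = np.random.default_rng(rng_seed)
    d = model.dimension

    if d == 1:
        ens = _sample_centroids_1d(model, system, n, mcmc, rng, profile, solver_opts)
    else:
        ens = _sample_centroids_nd(model, system, n, mcmc, rng, solver_opts)
    return ens


def _sample_centroids_1d(model, system, n, mcmc, rng, profile, solver_opts):
    M, beta = system.mass, system.beta
    n_chains = max(1, mcmc.n_chains)
    per_chain = -(-n // n_chains)  # ceil

    if profile is not None:
        def w1_of(x):
            return profile.try_W1(float(x))
    else:
        cache: dict[float, EffectiveFrequencyResult] = {}

        def w1_of(x):
            x = float(x)
            if x in cache:
                return cache[x].W1
            res = solve_effective_frequency(model, x, system, **(solver_opts or {}))
            if not res.converged or not np.isfinite(res.W1):
                logger.warning("FK solve failed at proposed xc=%g; proposal rejected", x)
                return None
            cache[x] = res
            return res.W1

    # starting points: potential minima, alternating sign for symmetric wells
    x0 = _find_start(model)
    starts = np.array([x0 * (1 if k % 2 == 0 else -1) for k in range(n_chains)]) \
        if mcmc.start is None else np.full(n_chains, float(np.atleast_1d(mcmc.start)[0]))
    # thermal length scale as the initial proposal step
    step = mcmc.step or max(1e-3, math.sqrt(1.0 / (beta * M)) )

    xs_out = np.empty(n_chains * per_chain)
    w1_out = np.empty_like(xs_out)
    chain_out = np.empty(xs_out.shape, dtype=int)
    n_acc_total = 0
    n_tot_total = 0

    for ci in range(n_chains):
        x = float(starts[ci])
        w1 = w1_of(x)
        if w1 is None:
            # nudge until valid
            for _ in range(100):
                x += 0.1 * step * rng.standard_normal()
                w1 = w1_of(x)
                if w1 is not None:
                    break
            if w1 is None:
                raise InvalidParameterError("could not find a valid MCMC start point")
        st = step
        acc_win = 0
        # burn-in with step auto-tuning, frozen afterwards
        for it in range(mcmc.burn_in):
            xp = x + st * rng.standard_normal()
            w1p = w1_of(xp)
            if w1p is not None and math.log(rng.random() + 1e-300) < -beta * (w1p - w1):
                x, w1 = xp, w1p
                acc_win += 1
            if (it + 1) % 50 == 0:
                rate = acc_win / 50.0
                if rate < 0.30:
                    st *= 0.8
                elif rate > 0.50:
                    st *= 1.25
                acc_win = 0
        n_acc = 0
        n_tot = 0
        k = 0
        while k < per_chain:
            for _ in range(max(1, mcmc.thinning)):
                xp = x + st * rng.standard_normal()
                w1p = w1_of(xp)
                n_tot += 1
                if w1p is not None and math.log(rng.random() + 1e-300) < -beta * (w1p - w1):
                    x, w1 = xp, w1p
                    n_acc += 1
            idx = ci * per_chain + k
            xs_out[idx] = x
            w1_out[idx] = w1
            chain_out[idx] = ci
            k += 1
        n_acc_total += n_acc
        n_tot_total += n_tot

    xs_out = xs_out[:n_chains * per_chain]
    pc = rng.normal(0.0, math.sqrt(M / beta), size=xs_out.size)

    if profile is not None:
        om2 = profile.omega2(xs_out)
        a2 = profile.a2(xs_out)
        al = profile.alpha(xs_out)
        vq = profile.var_q(xs_out)
        vp = profile.var_p(xs_out)
    else:
        om2 = np.empty_like(xs_out)
        a2 = np.empty_like(xs_out)
        al = np.empty_like(xs_out)
        vq = np.empty_like(xs_out)
        vp = np.empty_like(xs_out)
        for i, x in enumerate(xs_out):
            res = cache.get(float(x)) or solve_effective_frequency(
                model, x, system, **(solver_opts or {}))
            om2[i], a2[i], al[i] = res.omega2, res.a2, res.alpha
            vq[i], vp[i] = res.var_q, res.var_p_qdo

    logw = -beta * (pc**2 / (2 * M) + w1_out)
    acc_rate = n_acc_total / max(1, n_tot_total)
    logger.info("centroid MCMC acceptance rate: %.3f", acc_rate)
    ens = CentroidEnsemble(system, xs_out, pc, om2, a2, al, vq, vp, w1_out,
                           logw, chain_out, acceptance_rate=acc_rate)
    return ens


def _sample_centroids_nd(model, system, n, mcmc, rng, solver_opts):
    """Multi-dimensional Metropolis walk; per-proposal matrix FK solves."""
    d = model.dimension
    beta = system.beta
    masses = system.masses if system.masses.size == d else np.full(d, system.mass)
    opts = dict(solver_opts or {})
    opts.setdefault("n_samples", 500)
    if mcmc.start is not None:
        x = np.asarray(mcmc.start, float).copy()
    elif model.box_length is not None:
        x = np.arange(d) * (model.box_length / d)  # lattice start, no overlaps
    else:
        x = np.zeros(d)
    res = effective_frequency_matrix(model, x, system, rng=rng, **opts)
    step = mcmc.step or math.sqrt(1.0 / (beta * float(np.mean(masses))))
    n_acc = 0
    n_tot = 0
    rows = []
    effs = []
    chain = []
    total_sweeps = mcmc.burn_in + n * max(1, mcmc.thinning)
    for it in range(total_sweeps):
        xp = x + step * rng.standard_normal(d)
        try:
            resp = effective_frequency_matrix(model, xp, system, rng=rng, **opts)
            ok = resp.converged and np.isfinite(resp.W1)
        except Exception:
            ok = False
        n_tot += 1
        if ok and math.log(rng.random() + 1e-300) < -beta * (resp.W1 - res.W1):
            x, res = xp, resp
            n_acc += 1
        if it >= mcmc.burn_in and (it - mcmc.burn_in + 1) % max(1, mcmc.thinning) == 0:
            rows.append(x.copy())
            effs.append(res)
            chain.append(0)
            if len(rows) >= n:
                break
    xs = np.array(rows)
    pc = rng.normal(0.0, np.sqrt(masses / beta), size=xs.shape)
    om2 = np.array([e.omega2 for e in effs])
    a2 = np.array([e.a2 for e in effs])
    al = np.array([e.alpha for e in effs])
    vq = np.array([e.var_q for e in effs])
    vp = np.array([e.var_p_qdo for e in effs])
    W1 = np.array([e.W1 for e in effs])
    logw = -beta * (np.sum(pc**2 / (2 * masses), axis=1) + W1)
    return CentroidEnsemble(system, xs, pc, om2, a2, al, vq, vp, W1, logw,
                            np.array(chain), acceptance_rate=n_acc / max(1, n_tot))


def sample_fluctuation_cloud(
    ens: CentroidEnsemble, n_planets: int, rng_seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized QDO fluctuation sampling for a whole 1D ensemble.

    Returns (q, p) arrays of shape (n_centroids, n_planets).
    """
    if np.any(~(ens.var_p > 0)):
        raise BarrierValidityError(
            "ensemble contains barrier modes; use sample_barrier_marginal"
        )
    rng = np.random.default_rng(rng_seed)
    shape = (ens.n, n_planets)
    q = ens.xc[:, None] + np.sqrt(ens.var_q)[:, None] * rng.standard_normal(shape)
    p = ens.pc[:, None] + np.sqrt(ens.var_p)[:, None] * rng.standard_normal(shape)
    return q, p


def sample_mixed_cloud(
    ens: CentroidEnsemble, n_planets: int, rng_seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Fluctuation sampling tolerating barrier centroids (1D ensembles).

    Positive-frequency centroids get the regular QDO Gaussians; barrier
    centroids (var_p <= 0) get the marginal branch with the centroid
    momentum integrated out: q from the continued position Gaussian, p from
    the combined Gaussian of variance M/beta + var_p (requires
    hbar*|Omega|*beta < pi per sample).  Barrier rows have pc reset to 0,
    consistent with pc having been integrated out.
    """
    rng = np.random.default_rng(rng_seed)
    shape = (ens.n, n_planets)
    barrier = ~(ens.var_p > 0)
    M, beta, hbar = ens.system.mass, ens.system.beta, ens.system.hbar
    var_p_eff = np.where(barrier, M / beta + ens.var_p, ens.var_p)
    if np.any(var_p_eff <= 0):
        x = hbar * np.sqrt(np.abs(ens.omega2[var_p_eff <= 0])) * beta
        raise BarrierValidityError(
            "barrier sampling requires hbar*|Omega|*beta < pi; worst sample "
            f"has {np.max(x):.6g}"
        )
    ens.pc = np.where(barrier, 0.0, ens.pc)
    q = ens.xc[:, None] + np.sqrt(ens.var_q)[:, None] * rng.standard_normal(shape)
    p = ens.pc[:, None] + np.sqrt(var_p_eff)[:, None] * rng.standard_normal(shape)
    return q, p


def sample_qdo_fluctuations(
    c: CentroidSample, n: int, rng_seed: int | np.random.Generator = 0
) -> list[PhasePoint]:
    """Independent Gaussian planets around one centroid (all modes Omega^2>0)."""
    eff = c.eff
    var_q = np.atleast_1d(np.asarray(eff.var_q, float))
    var_p = np.atleast_1d(np.asarray(eff.var_p_qdo, float))
    if np.any(~(var_p > 0)):
        raise BarrierValidityError(
            "barrier mode present; use sample_barrier_marginal"
        )
    rng = np.random.default_rng(rng_seed)
    d = var_q.size
    qs = c.xc + np.sqrt(var_q) * rng.standard_normal((n, d))
    ps = c.pc + np.sqrt(var_p) * rng.standard_normal((n, d))
    return [PhasePoint(q=qs[i], p=ps[i], parent=c) for i in range(n)]


def sample_barrier_marginal(
    c: CentroidSample,
    system: ThermalSystem,
    n: int,
    rng_seed: int | np.random.Generator = 0,
) -> list[PhasePoint]:
    """Barrier-branch sampling with the centroid momentum integrated out.

    Position planets come from the (positive) continued position Gaussian;
    momenta from the combined Gaussian of variance M/beta + var_p_qdo, which
    is positive exactly when hbar*|Omega|*beta < pi.
    """
    eff = c.eff
    om2 = float(np.atleast_1d(eff.omega2)[0])
    if om2 >= 0:
        raise BarrierValidityError("sample_barrier_marginal requires Omega^2 < 0")
    M = system.mass
    x = system.hbar * math.sqrt(-om2) * system.beta
    var_comb = M / system.beta + float(np.atleast_1d(eff.var_p_qdo)[0])
    if x >= math.pi or var_comb <= 0:
        raise BarrierValidityError(
            f"barrier sampling requires hbar*|Omega|*beta < pi; got {x:.6g}"
        )
    rng = np.random.default_rng(rng_seed)
    var_q = float(np.atleast_1d(eff.var_q)[0])
    qs = float(c.xc[0]) + math.sqrt(var_q) * rng.standard_normal(n)
    ps = math.sqrt(var_comb) * rng.standard_normal(n)
    return [PhasePoint(q=np.array([qs[i]]), p=np.array([ps[i]]), parent=c)
            for i in range(n)]


def barrier_momentum_variance(omega2: float, system: ThermalSystem) -> float:
    """Combined momentum variance M/beta + M*Omega*alpha*hbar/2, continued.

    Positive iff hbar*|Omega|*beta < pi; used by the validity-scan tests.
    """
    from .fk_core import quantum_widths

    _, _, var_p = quantum_widths(omega2, system)
    return system.mass / system.beta + var_p


# ---------------------------------------------------------------------------
# operator estimators
# ---------------------------------------------------------------------------

class Estimator:
    """A-side estimator for Eq.-(3)-type averages, vectorized over planets.

    ``standard`` flavor carries the Moyal-product correction of the QDO
    Gaussian (imaginary parts proportional to the fluctuation away from the
    centroid); ``kubo`` flavor uses the centroid variables themselves.
    """

    def __init__(self, kind: str, flavor: str):
        self.kind = kind
        self.flavor = flavor

    def __call__(self, q, p, ens: CentroidEnsemble | CentroidSample):
        if isinstance(ens, CentroidSample):
            xc = ens.xc
            pc = ens.pc
            var_q = np.asarray(ens.eff.var_q, float)
            var_p = np.asarray(ens.eff.var_p_qdo, float)
            M = ens.eff.mass
            hbar = 1.0
            system = None
        else:
            xc = ens.xc[:, None]
            pc = ens.pc[:, None]
            var_q = ens.var_q[:, None]
            var_p = ens.var_p[:, None]
            M = ens.system.mass
            hbar = ens.system.hbar
            system = ens.system
        if system is not None:
            hbar = system.hbar
        q = np.asarray(q, float)
        p = np.asarray(p, float)
        k, f = self.kind, self.flavor
        if f == "kubo":
            if k == "identity":
                return np.ones_like(q, dtype=complex)
            if k == "position":
                return (xc + 0.0 * q).astype(complex)
            if k == "momentum":
                return (pc + 0.0 * p).astype(complex)
            if k == "velocity":
                return (pc / M + 0.0 * p).astype(complex)
            raise EstimatorError(f"unsupported kubo estimator '{k}'")
        if f == "standard":
            if k == "identity":
                return np.ones_like(q, dtype=complex)
            if np.any(~(var_p > 0)):
                raise BarrierValidityError(
                    "standard-flavor estimators undefined on barrier modes"
                )
            if k == "position":
                # q - i(p-pc)/(M Omega alpha) == q - i*hbar*(p-pc)/(2 var_p)
                return q - 1j * hbar * (p - pc) / (2.0 * var_p)
            if k == "momentum":
                # p + i M Omega (q-xc)/alpha == p + i*hbar*(q-xc)/(2 var_q)
                return p + 1j * hbar * (q - xc) / (2.0 * var_q)
            if k == "velocity":
                return (p + 1j * hbar * (q - xc) / (2.0 * var_q)) / M
            raise EstimatorError(f"unsupported standard estimator '{k}'")
        raise EstimatorError(f"unsupported flavor '{f}'")


def operator_estimator(kind: str, flavor: str = "standard") -> Estimator:
    """Factory for A-side operator estimators.

    kind in {identity, position, momentum, velocity}; flavor in
    {standard, kubo}.
    """
    if kind not in ("identity", "position", "momentum", "velocity"):
        raise EstimatorError(f"unknown operator kind '{kind}'")
    if flavor not in ("standard", "kubo"):
        raise EstimatorError(f"unknown flavor '{flavor}'")
    return Estimator(kind, flavor)


# ---------------------------------------------------------------------------
# centroid-integrated Boltzmann-Wigner distribution on a grid
# ---------------------------------------------------------------------------

def boltzmann_wigner_on_grid(
    profile: FKProfile,
    system: ThermalSystem,
    q_grid: np.ndarray,
    p_grid: np.ndarray,
    xc_grid: np.ndarray | None = None,
) -> np.ndarray:
    """Centroid-integrated FK Wigner distribution, unnormalized, on a grid.

    Integrates exp(-beta W1(xc)) times the QDO Gaussian over centroid
    position (trapezoid on xc_grid), with the centroid momentum integral
    done analytically (Gaussian convolution: the p marginal has variance
    M/beta + var_p(xc)).  Rows index q, columns p.
    """
    if xc_grid is None:
        lo, hi = profile.grid[0], profile.grid[-1]
        xc_grid = np.linspace(lo, hi, 601)
    M, beta = system.mass, system.beta
    W1 = profile.W1(xc_grid)
    al = profile.alpha(xc_grid)
    vq = profile.var_q(xc_grid)
    vp = profile.var_p(xc_grid)
    s2 = M / beta + vp  # combined momentum variance
    if np.any(s2 <= 0):
        raise BarrierValidityError("momentum convolution undefined (variance <= 0)")
    wgt = np.exp(-beta * (W1 - W1.min())) * (2.0 / al) * np.sqrt(vp * (M / beta) / s2)
    out = np.empty((q_grid.size, p_grid.size))
    pq = np.exp(-0.5 * p_grid[None, :] ** 2 / s2[:, None])  # (xc, p)
    for i, qv in enumerate(q_grid):
        gq = np.exp(-0.5 * (qv - xc_grid) ** 2 / vq)  # (xc,)
        out[i] = np.trapezoid((wgt * gq)[:, None] * pq, xc_grid, axis=0)
    return out


# ---------------------------------------------------------------------------
# ensemble archive
# ---------------------------------------------------------------------------

def save_ensemble(path, ens: CentroidEnsemble, planets=None, meta: dict | None = None):
    """Persist an ensemble (and optional planet cloud) to an .npz archive."""
    data = {
        "xc": ens.xc, "pc": ens.pc, "omega2": ens.omega2, "a2": ens.a2,
        "alpha": ens.alpha, "var_q": ens.var_q, "var_p": ens.var_p,
        "W1": ens.W1, "log_weight": ens.log_weight, "chain_id": ens.chain_id,
        "beta": np.array(ens.system.beta), "masses": ens.system.masses,
        "hbar": np.array(ens.system.hbar),
        "acceptance_rate": np.array(ens.acceptance_rate),
    }
    if planets is not None:
        data["planet_q"], data["planet_p"] = planets
    for k, v in (meta or {}).items():
        data[f"meta_{k}"] = np.asarray(v)
    np.savez(path, **data)


def load_ensemble(path):
    """Load an ensemble archive; returns (CentroidEnsemble, planets|None, meta)."""
    with np.load(path, allow_pickle=False) as z:
        system = ThermalSystem(float(z["beta"]), z["masses"], float(z["hbar"]))
        ens = CentroidEnsemble(
            system, z["xc"], z["pc"], z["omega2"], z["a2"], z["alpha"],
            z["var_q"], z["var_p"], z["W1"], z["log_weight"], z["chain_id"],
            acceptance_rate=float(z["acceptance_rate"]),
        )
        planets = None
        if "planet_q" in z:
            planets = (z["planet_q"], z["planet_p"])
        meta = {k[5:]: z[k] for k in z.files if k.startswith("meta_")}
    return ens, planets, meta
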