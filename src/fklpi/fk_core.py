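"""Feynman-Kleinert variational effective frequencies and centroid potential.

The local harmonic description of quantum fluctuations around a centroid xc
is obtained by iterating two coupled relations until self-consistency:

* the Gaussian smearing width
      a^2(Omega) = [ (x/2) coth(x/2) - 1 ] / (M Omega^2 beta),  x = hbar*Omega*beta,
  which tends to hbar^2 beta / (12 M) at high temperature and to the
  ground-state width hbar/(2 M Omega) at low temperature;

* the smeared Hessian
      Omega^2(a^2) = (1/M) E[ V''(xc + y) ],   y ~ Normal(0, a^2),
  evaluated either by Gauss-Hermite quadrature or, "black-box" style, by
  Monte Carlo gradient sampling of (1/ M a^2) E[ V'(xc+y) y ].

At a barrier Omega^2 < 0 and the expressions are analytically continued
(coth -> cot); the continuation is real and positive for
hbar*|Omega|*beta < 2*pi.  The centroid potential

    W1(xc) = kT ln[ sinh(x/2)/(x/2) ] + V_smeared(xc) - (1/2) M Omega^2 a^2

defines the classical-like centroid density exp(-beta pc^2/2M - beta W1(xc)).
"""

from __future__ import annotations

import dataclasses
import functools
import math

import numpy as np

from .errors import ContinuationRangeError, ConvergenceError, InvalidParameterError
from .potentials import PotentialModel

__all__ = [
    "ThermalSystem",
    "EffectiveFrequencyResult",
    "alpha_parameter",
    "smearing_width",
    "quantum_widths",
    "smeared_hessian_quadrature",
    "smeared_hessian_force_sampling",
    "smeared_potential_quadrature",
    "solve_effective_frequency",
    "centroid_potential",
    "centroid_log_weight",
    "effective_frequency_matrix",
    "FKProfile",
]


@dataclasses.dataclass(frozen=True)
class ThermalSystem:
    """Ensemble context: inverse temperature, masses and the hbar convention.

    ``masses`` is one positive mass per degree of freedom.  Internal units
    put hbar = 1 by default; whatever unit system is chosen here is used
    consistently everywhere else.
    """

    beta: float
    masses: np.ndarray
    hbar: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "masses", np.atleast_1d(np.asarray(self.masses, float)))
        if not (self.beta > 0 and np.isfinite(self.beta)):
            raise InvalidParameterError("beta must be positive and finite")
        if np.any(self.masses <= 0):
            raise InvalidParameterError("all masses must be positive")
        if not self.hbar > 0:
            raise InvalidParameterError("hbar must be positive")

    @property
    def kT(self) -> float:
        return 1.0 / self.beta

    @property
    def mass(self) -> float:
        """Convenience scalar mass for 1D systems."""
        return float(self.masses[0])


@dataclasses.dataclass
class EffectiveFrequencyResult:
    """Converged FK data at one centroid.

    ``alpha`` is stored as a real number for Omega^2 > 0 and NaN on the
    barrier branch; the analytically continued Gaussian widths that sampling
    actually needs are kept separately:

    * ``var_q``  = hbar*alpha/(2 M Omega)      (positive on both branches),
    * ``var_p_qdo`` = M*Omega*alpha*hbar/2     (negative at a barrier).
    """

    xc: np.ndarray
    omega2: float | np.ndarray
    a2: float | np.ndarray
    alpha: float | np.ndarray
    var_q: float | np.ndarray
    var_p_qdo: float | np.ndarray
    W1: float
    smeared_V: float
    iterations: int
    converged: bool
    barrier: bool
    mass: float | np.ndarray
    mode_vectors: np.ndarray | None = None

    @property
    def omega(self):
        return np.sqrt(np.abs(self.omega2))


# ---------------------------------------------------------------------------
# scalar building blocks
# ---------------------------------------------------------------------------

def _num_u(u: float) -> float:
    """(x/2)coth(x/2) - 1 as an analytic function of u = x^2 = (hbar*Omega*beta)^2.

    Continues to u < 0 as (theta)cot(theta)-1 with theta = sqrt(-u)/2; the
    Taylor series in u is used near zero to avoid cancellation.
    """
    if abs(u) < 1e-6:
        # y coth y - 1 = y^2/3 - y^4/45 + 2 y^6/945, y = x/2, y^2 = u/4
        y2 = 0.25 * u
        return y2 / 3.0 - y2**2 / 45.0 + 2.0 * y2**3 / 945.0
    if u > 0:
        y = 0.5 * math.sqrt(u)
        return y / math.tanh(y) - 1.0
    th = 0.5 * math.sqrt(-u)
    if th >= math.pi:
        raise ContinuationRangeError(
            f"hbar*|Omega|*beta = {2*th:.6g} >= 2*pi: smearing-width continuation "
            "out of range"
        )
    return th / math.tan(th) - 1.0


def alpha_parameter(omega2: float, system: ThermalSystem) -> float:
    """alpha = coth(hbar*Omega*beta/2) - 2/(hbar*Omega*beta), in (0, 1).

    Only defined for Omega^2 > 0; barrier modes must use the continued
    widths from :func:`quantum_widths`.
    """
    if not (omega2 > 0 and np.isfinite(omega2)):
        raise InvalidParameterError(
            "alpha_parameter requires omega2 > 0; use quantum_widths for barriers"
        )
    x = system.hbar * math.sqrt(omega2) * system.beta
    if x < 1e-3:
        # coth(x/2) = 2/x + x/6 - x^3/360 + ...
        return x / 6.0 - x**3 / 360.0
    return 1.0 / math.tanh(0.5 * x) - 2.0 / x


def smearing_width(omega2: float, system: ThermalSystem, mass: float | None = None) -> float:
    """FK smearing width a^2(Omega); analytic continuation for Omega^2 < 0.

    Positive for hbar*|Omega|*beta < 2*pi on the barrier branch; raises
    ContinuationRangeError beyond.
    """
    M = system.mass if mass is None else mass
    u = (system.hbar * system.beta) ** 2 * omega2
    num = _num_u(u)
    if abs(u) < 1e-6:
        # a^2 = hbar^2 beta/M * num/u -> hbar^2 beta/(12 M) as u -> 0
        y2 = 0.25 * u
        series = 1.0 / 12.0 - y2 / 180.0 + y2**2 * (2.0 / 3780.0)
        return system.hbar**2 * system.beta / M * series
    return num / (M * omega2 * system.beta)


def quantum_widths(
    omega2: float, system: ThermalSystem, mass: float | None = None
) -> tuple[float, float, float]:
    """(alpha, var_q, var_p_qdo) for either sign of Omega^2.

    var_q = hbar*alpha/(2 M Omega) and var_p_qdo = M*Omega*alpha*hbar/2 are
    the QDO Wigner marginal variances.  On the barrier branch alpha is
    imaginary; the products above stay real, var_q > 0 and var_p_qdo < 0
    (for hbar*|Omega|*beta < 2*pi), and alpha is reported as NaN.
    """
    M = system.mass if mass is None else mass
    hbar, beta = system.hbar, system.beta
    if omega2 > 0:
        w = math.sqrt(omega2)
        al = alpha_parameter(omega2, system)
        return al, hbar * al / (2.0 * M * w), 0.5 * M * w * al * hbar
    if omega2 == 0.0:
        # alpha/Omega -> hbar*beta/6, alpha*Omega -> 0
        return 0.0, hbar**2 * beta / (12.0 * M), 0.0
    w = math.sqrt(-omega2)
    th = 0.5 * hbar * w * beta
    if th >= math.pi:
        raise ContinuationRangeError(
            f"hbar*|Omega|*beta = {2*th:.6g} >= 2*pi: continued widths undefined"
        )
    g = 1.0 / th - 1.0 / math.tan(th)  # = (1/theta - cot theta) > 0 for theta < pi
    return math.nan, hbar * g / (2.0 * M * w), -0.5 * M * w * hbar * g


@functools.lru_cache(maxsize=8)
def _gh_nodes(order: int):
    t, w = np.polynomial.hermite.hermgauss(order)
    return t, w / math.sqrt(math.pi)


def _gauss_expectation(f, xc: float, a2: float, order: int) -> float:
    """E[f(xc+y)], y ~ N(0, a2), by Gauss-Hermite quadrature."""
    t, w = _gh_nodes(order)
    y = math.sqrt(2.0 * a2) * t
    vals = np.asarray(f(xc + y), dtype=float)
    if not np.all(np.isfinite(vals)):
        raise InvalidParameterError("non-finite integrand in Gaussian smearing")
    return float(np.dot(w, vals))


def smeared_hessian_quadrature(
    model: PotentialModel,
    xc: float,
    a2: float,
    mass: float = 1.0,
    order: int = 40,
    self_check: bool = True,
) -> float:
    """Omega^2 candidate (1/M) E[V''(xc+y)] by Gauss-Hermite quadrature.

    Exact for polynomial V'' up to the quadrature order.  A cheap
    self-consistency check doubles the order when 40 vs 80 disagree beyond
    1e-8 relative.
    """
    if not a2 > 0:
        raise InvalidParameterError("a2 must be positive")
    est = _gauss_expectation(model.d2v, xc, a2, order) / mass
    if self_check:
        est2 = _gauss_expectation(model.d2v, xc, a2, 2 * order) / mass
        if abs(est2 - est) > 1e-8 * max(1.0, abs(est2)):
            est = est2
    return est


def smeared_potential_quadrature(
    model: PotentialModel, xc: float, a2: float, order: int = 40
) -> float:
    """Smeared potential E[V(xc+y)], y ~ N(0, a2) (Eq.-(11) form, V for V'')."""
    if not a2 > 0:
        raise InvalidParameterError("a2 must be positive")
    return _gauss_expectation(model.v, xc, a2, order)


def smeared_hessian_force_sampling(
    model: PotentialModel,
    xc: float,
    a2: float,
    n_samples: int = 2500,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Monte Carlo "gradient sampling" of the smeared Hessian.

    Integration by parts turns the smeared Hessian into
    (1/(M a^2)) E[V'(xc+y) y], which needs force calls only.  Returns the
    unbiased estimate and its standard error.  The default n_samples = 2500
    is the liquid-scale working value.
    """
    if n_samples < 2:
        raise InvalidParameterError("n_samples must be >= 2")
    if not a2 > 0:
        raise InvalidParameterError("a2 must be positive")
    rng = np.random.default_rng(rng)
    y = rng.normal(0.0, math.sqrt(a2), size=n_samples)
    per_sample = np.asarray(model.dv(xc + y)) * y / a2
    if not np.all(np.isfinite(per_sample)):
        raise InvalidParameterError("non-finite force samples in gradient sampling")
    est = float(np.mean(per_sample))
    sem = float(np.std(per_sample, ddof=1) / math.sqrt(n_samples))
    return est, sem


# ---------------------------------------------------------------------------
# the self-consistent solve (1D)
# ---------------------------------------------------------------------------

def solve_effective_frequency(
    model: PotentialModel,
    xc: float,
    system: ThermalSystem,
    *,
    tol: float = 1e-8,
    atol: float = 1e-12,
    max_iter: int = 200,
    smearing: str = "quadrature",
    n_force_samples: int = 2500,
    rng: np.random.Generator | int | None = None,
    quadrature_order: int = 40,
    raise_on_failure: bool = False,
) -> EffectiveFrequencyResult:
    """Self-consistent Omega^2(xc) for a 1D model.

    Fixed-point iteration between the width and smeared-Hessian relations,
    initialized from the bare Hessian (or from the high-T width when the
    bare curvature is non-positive).  A damping factor 0.5 kicks in when the
    iteration oscillates.  Non-convergence and continuation-range failures
    are flagged on the result rather than silently ignored (or raised when
    ``raise_on_failure``).
    """
    xc = float(np.atleast_1d(xc)[0])
    M = system.mass
    if smearing == "force_sampling":
        rng = np.random.default_rng(rng)

        def omega2_of(a2):
            return smeared_hessian_force_sampling(model, xc, a2, n_force_samples, rng)[0]
    elif smearing == "quadrature":

        def omega2_of(a2):
            return smeared_hessian_quadrature(
                model, xc, a2, mass=M, order=quadrature_order
            )
    else:
        raise InvalidParameterError(f"unknown smearing mode '{smearing}'")

    bare = float(model.d2v(xc)) / M
    if bare > 0:
        w2 = bare
    else:
        a2_0 = system.hbar**2 * system.beta / (12.0 * M)
        w2 = omega2_of(a2_0)

    prev_step = 0.0
    converged = False
    it = 0
    a2 = None
    try:
        for it in range(1, max_iter + 1):
            a2 = smearing_width(w2, system)
            w2_new = omega2_of(a2)
            step = w2_new - w2
            if prev_step * step < 0:  # oscillation -> damp
                w2_new = w2 + 0.5 * step
                step = w2_new - w2
            prev_step = step
            if abs(step) <= tol * abs(w2_new) + atol:
                w2 = w2_new
                a2 = smearing_width(w2, system)
                converged = True
                break
            w2 = w2_new
    except ContinuationRangeError:
        if raise_on_failure:
            raise
        return EffectiveFrequencyResult(
            xc=np.array([xc]), omega2=w2, a2=math.nan, alpha=math.nan,
            var_q=math.nan, var_p_qdo=math.nan, W1=math.nan, smeared_V=math.nan,
            iterations=it, converged=False, barrier=w2 < 0, mass=M,
        )
    if not converged:
        if raise_on_failure:
            raise ConvergenceError(
                f"effective frequency at xc={xc} not converged in {max_iter} iterations"
            )

    alpha, var_q, var_p = quantum_widths(w2, system)
    res = EffectiveFrequencyResult(
        xc=np.array([xc]), omega2=w2, a2=a2, alpha=alpha, var_q=var_q,
        var_p_qdo=var_p, W1=math.nan, smeared_V=math.nan, iterations=it,
        converged=converged, barrier=w2 < 0, mass=M,
    )
    res.W1 = centroid_potential(res, model, system, order=quadrature_order)
    return res


def _log_sinh_ratio(u: float) -> float:
    """ln[sinh(x/2)/(x/2)] as analytic function of u = x^2; sin form for u<0."""
    if abs(u) < 1e-6:
        y2 = 0.25 * u
        return y2 / 6.0 - y2**2 / 180.0
    if u > 0:
        y = 0.5 * math.sqrt(u)
        # numerically safe for large y: ln(sinh y / y) = y - ln(2y) + ln(1-e^{-2y})
        return y - math.log(2.0 * y) + math.log1p(-math.exp(-2.0 * y))
    th = 0.5 * math.sqrt(-u)
    if th >= math.pi:
        raise ContinuationRangeError(
            f"hbar*|Omega|*beta = {2*th:.6g} >= 2*pi in centroid potential"
        )
    return math.log(math.sin(th) / th)


def centroid_potential(
    result: EffectiveFrequencyResult,
    model: PotentialModel,
    system: ThermalSystem,
    order: int = 40,
) -> float:
    """FK centroid potential W1 at the result's centroid.

    W1 = kT ln[sinh(x/2)/(x/2)] + V_a2(xc) - (1/2) M Omega^2 a^2, with the
    smeared potential computed with the same width a^2 as the frequency
    solve, and the sin form on the barrier branch.  The term
    (1/2) M Omega^2 a^2 = num(x)/(2 beta) is evaluated directly from the
    width numerator, which is regular through Omega^2 = 0.
    """
    xc = float(np.atleast_1d(result.xc)[0])
    u = (system.hbar * system.beta) ** 2 * result.omega2
    ln_term = system.kT * _log_sinh_ratio(u)
    if result.a2 > 0 and np.isfinite(result.a2):
        Vs = smeared_potential_quadrature(model, xc, result.a2, order=order)
    else:
        Vs = float(model.v(xc))
    result.smeared_V = Vs
    half_MW2a2 = _num_u(u) / (2.0 * system.beta)
    return ln_term + Vs - half_MW2a2


def centroid_log_weight(xc, pc, W1: float, system: ThermalSystem) -> float:
    """Unnormalized log of the FK centroid density, -beta(pc^2/2M) - beta W1.

    Normalization (the partition function) is never computed; Monte Carlo
    only ever uses weight differences.
    """
    pc = np.atleast_1d(np.asarray(pc, float))
    kin = float(np.sum(pc**2 / (2.0 * system.masses)))
    return -system.beta * (kin + W1)


# ---------------------------------------------------------------------------
# multi-dimensional effective-frequency matrix
# ---------------------------------------------------------------------------

def effective_frequency_matrix(
    model: PotentialModel,
    xc,
    system: ThermalSystem,
    *,
    tol: float = 1e-6,
    max_iter: int = 100,
    n_samples: int = 2000,
    rng: np.random.Generator | int | None = None,
    zero_mode_tol: float = 1e-8,
) -> EffectiveFrequencyResult:
    """Self-consistent normal-mode frequencies for dimension >= 2.

    Iterates (i) the mass-weighted Gaussian-smeared Hessian matrix, sampled
    with per-mode widths, (ii) its diagonalization into mode frequencies
    and vectors, (iii) per-mode widths from the 1D relation.  Zero
    (translational) modes get the free-particle width hbar^2*beta/12.
    The same Gaussian draw is reused across iterations (common random
    numbers) so the fixed-point map is deterministic and convergence is
    well defined; constant-Hessian (harmonic/bilinear) problems are exact
    after one iteration regardless of n_samples.
    """
    xc = np.asarray(xc, dtype=float)
    d = xc.size
    if d < 2:
        raise InvalidParameterError("effective_frequency_matrix requires dimension >= 2")
    if system.masses.size == 1:
        masses = np.full(d, system.mass)
    else:
        masses = system.masses
    sqm = np.sqrt(masses)
    rng = np.random.default_rng(rng)
    xi = rng.standard_normal((n_samples, d))  # frozen across iterations

    def mode_widths(lam):
        a2 = np.empty_like(lam)
        for k, l in enumerate(lam):
            if abs(l) < zero_mode_tol:
                a2[k] = system.hbar**2 * system.beta / 12.0
            else:
                a2[k] = smearing_width(l, system, mass=1.0)
        return a2

    def mw_hessian(x):
        H = model.hessian(x)
        return H / np.outer(sqm, sqm)

    H0 = mw_hessian(xc)
    lam, U = np.linalg.eigh(H0)
    smeared_V = float("nan")
    converged = False
    it = 0
    H_prev = H0
    prev_delta = math.inf
    for it in range(1, max_iter + 1):
        a2 = mode_widths(lam)
        # displacements in mass-weighted coords: y = U @ (sqrt(a2)*xi)
        y = (U * np.sqrt(a2)) @ xi.T  # (d, n)
        X = xc[None, :] + (y / sqm[:, None]).T
        if hasattr(model, "hessians_batch"):
            Hbar = np.mean(model.hessians_batch(X), axis=0) / np.outer(sqm, sqm)
            Vbar = float(np.mean(model.energies_batch(X)))
        else:
            Hbar = np.zeros((d, d))
            Vbar = 0.0
            for x in X:
                Hbar += mw_hessian(x)
                Vbar += model.value(x)
            Hbar /= n_samples
            Vbar /= n_samples
        lam_new, U_new = np.linalg.eigh(Hbar)
        delta = np.max(np.abs(lam_new - lam)) / max(1.0, np.max(np.abs(lam_new)))
        if delta >= prev_delta:  # oscillating -> damp the Hessian update
            Hbar = 0.5 * (Hbar + H_prev)
            lam_new, U_new = np.linalg.eigh(Hbar)
            delta = np.max(np.abs(lam_new - lam)) / max(1.0, np.max(np.abs(lam_new)))
        H_prev = Hbar
        prev_delta = delta
        lam, U = lam_new, U_new
        smeared_V = Vbar
        if delta <= tol:
            converged = True
            break

    a2 = mode_widths(lam)
    alpha = np.empty(d)
    var_q = np.empty(d)
    var_p = np.empty(d)
    for k, l in enumerate(lam):
        if abs(l) < zero_mode_tol:
            alpha[k], var_q[k], var_p[k] = quantum_widths(0.0, system, mass=1.0)
        else:
            alpha[k], var_q[k], var_p[k] = quantum_widths(l, system, mass=1.0)

    beta = system.beta
    hbeta2 = (system.hbar * beta) ** 2
    W1 = smeared_V
    for l in lam:
        if abs(l) < zero_mode_tol:
            continue
        u = hbeta2 * l
        W1 += system.kT * _log_sinh_ratio(u) - _num_u(u) / (2.0 * beta)

    return EffectiveFrequencyResult(
        xc=xc, omega2=lam, a2=a2, alpha=alpha, var_q=var_q, var_p_qdo=var_p,
        W1=W1, smeared_V=smeared_V, iterations=it, converged=converged,
        barrier=bool(np.any(lam < -zero_mode_tol)), mass=np.ones(d),
        mode_vectors=U,
    )


# ---------------------------------------------------------------------------
# spline cache of the 1D FK solution
# ---------------------------------------------------------------------------

class FKProfile:
    """Cubic-spline cache of the 1D FK solution W1(xc), Omega^2(xc), widths.

    Built once per (model, beta) on a uniform centroid grid; the grid is
    grown transparently when a query falls outside it.  Grid points where
    the solve fails (barrier continuation out of range) split the domain
    into valid segments; queries inside an invalid gap raise
    ContinuationRangeError, and the samplers treat them as rejected moves.
    """

    def __init__(
        self,
        model: PotentialModel,
        system: ThermalSystem,
        x_min: float,
        x_max: float,
        n_points: int = 401,
        solver_opts: dict | None = None,
    ):
        from scipy.interpolate import CubicSpline

        self._CubicSpline = CubicSpline
        self.model = model
        self.system = system
        self.n_points = int(n_points)
        self.solver_opts = dict(solver_opts or {})
        self._build(float(x_min), float(x_max))

    def _solve_grid(self, xs: np.ndarray):
        cols = {k: np.full(xs.size, np.nan) for k in
                ("W1", "omega2", "a2", "alpha", "var_q", "var_p")}
        ok = np.zeros(xs.size, dtype=bool)
        iters = np.zeros(xs.size, dtype=int)
        for i, x in enumerate(xs):
            res = solve_effective_frequency(self.model, x, self.system, **self.solver_opts)
            iters[i] = res.iterations
            if res.converged and np.isfinite(res.W1):
                ok[i] = True
                cols["W1"][i] = res.W1
                cols["omega2"][i] = res.omega2
                cols["a2"][i] = res.a2
                cols["alpha"][i] = res.alpha
                cols["var_q"][i] = res.var_q
                cols["var_p"][i] = res.var_p_qdo
        return cols, ok, iters

    def _build(self, x_min: float, x_max: float) -> None:
        xs = np.linspace(x_min, x_max, self.n_points)
        cols, ok, iters = self._solve_grid(xs)
        self.grid = xs
        self.valid = ok
        self.iterations = iters
        self.columns = cols
        # contiguous valid segments (start, stop) index ranges
        self.segments = []
        self._splines = []
        i = 0
        while i < xs.size:
            if ok[i]:
                j = i
                while j + 1 < xs.size and ok[j + 1]:
                    j += 1
                if j - i + 1 >= 4:
                    seg = (i, j)
                    self.segments.append(seg)
                    sx = xs[i:j + 1]
                    # alpha is NaN on barrier points by convention; spline a
                    # zero-filled copy and re-mask on query
                    spl = {k: self._CubicSpline(sx, np.nan_to_num(cols[k][i:j + 1]))
                           for k in cols}
                    self._splines.append(spl)
                i = j + 1
            else:
                i += 1
        if not self.segments:
            raise ConvergenceError("FK profile: no valid centroid segment on the grid")

    def _segment_of(self, x: float) -> int:
        for s, (i, j) in enumerate(self.segments):
            if self.grid[i] <= x <= self.grid[j]:
                return s
        return -1

    def ensure_cover(self, x_min: float, x_max: float) -> None:
        """Transparently extend the grid so [x_min, x_max] is inside it."""
        lo, hi = self.grid[0], self.grid[-1]
        if x_min >= lo and x_max <= hi:
            return
        span = hi - lo
        new_lo = min(lo, x_min - 0.05 * span)
        new_hi = max(hi, x_max + 0.05 * span)
        dx = self.grid[1] - self.grid[0]
        self.n_points = max(self.n_points, int(round((new_hi - new_lo) / dx)) + 1)
        self._build(new_lo, new_hi)

    def _eval(self, key: str, x):
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        xf = np.atleast_1d(x)
        if xf.min() < self.grid[0] or xf.max() > self.grid[-1]:
            self.ensure_cover(float(xf.min()), float(xf.max()))
        out = np.empty_like(xf)
        done = np.zeros(xf.shape, dtype=bool)
        for (i, j), spl in zip(self.segments, self._splines):
            m = (xf >= self.grid[i]) & (xf <= self.grid[j]) & ~done
            if np.any(m):
                out[m] = spl[key](xf[m])
                done[m] = True
        if not np.all(done):
            bad = xf[~done]
            raise ContinuationRangeError(
                f"FK profile query at x={bad[:3]}... falls in a region where the "
                "effective-frequency solve is invalid (barrier continuation out of range)"
            )
        return float(out[0]) if scalar else out

    def try_W1(self, x: float) -> float | None:
        """W1(x) or None when x lies in an invalid region (for MC rejection)."""
        try:
            return self._eval("W1", x)
        except ContinuationRangeError:
            return None

    def W1(self, x):
        return self._eval("W1", x)

    def dW1(self, x):
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        xf = np.atleast_1d(x)
        if xf.min() < self.grid[0] or xf.max() > self.grid[-1]:
            self.ensure_cover(float(xf.min()), float(xf.max()))
        out = np.empty_like(xf)
        done = np.zeros(xf.shape, dtype=bool)
        for (i, j), spl in zip(self.segments, self._splines):
            m = (xf >= self.grid[i]) & (xf <= self.grid[j]) & ~done
            if np.any(m):
                out[m] = spl["W1"](xf[m], 1)
                done[m] = True
        if not np.all(done):
            raise ContinuationRangeError("dW1 query in invalid FK region")
        return float(out[0]) if scalar else out

    def omega2(self, x):
        return self._eval("omega2", x)

    def omega(self, x):
        return np.sqrt(np.abs(self._eval("omega2", x)))

    def a2(self, x):
        return self._eval("a2", x)

    def alpha(self, x):
        al = self._eval("alpha", x)
        om2 = self._eval("omega2", x)
        return np.where(np.asarray(om2) < 0, np.nan, al) if np.ndim(al) else (
            math.nan if om2 < 0 else al)

    def var_q(self, x):
        return self._eval("var_q", x)

    def var_p(self, x):
        return self._eval("var_p", x)

    def result_at(self, x: float) -> EffectiveFrequencyResult:
        """Interpolated EffectiveFrequencyResult (iterations = 0 marks cache)."""
        return EffectiveFrequencyResult(
            xc=np.array([x]), omega2=self._eval("omega2", x),
            a2=self._eval("a2", x), alpha=self._eval("alpha", x),
            var_q=self._eval("var_q", x), var_p_qdo=self._eval("var_p", x),
            W1=self._eval("W1", x), smeared_V=math.nan, iterations=0,
            converged=True, barrier=bool(self._eval("omega2", x) < 0),
            mass=self.system.mass,
        )

    def export_table(self) -> np.ndarray:
        """Scan table: columns xc, omega2, a2, alpha, W1, iterations, converged."""
        return np.column_stack([
            self.grid, self.columns["omega2"], self.columns["a2"],
            self.columns["alpha"], self.columns["W1"],
            self.iterations.astype(float), self.valid.astype(float),
        ])
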