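"""Potential energy surfaces: value, gradient and Hessian providers.

Three families are supported:

* analytic one-dimensional models (harmonic, quartic, double well, Morse,
  parabolic barrier) used both in production and as validation fixtures;
* a periodic one-dimensional pair liquid (truncated + shifted Lennard-Jones
  chain with the minimum-image convention);
* user-supplied ("external") force routines: any pure function
  ``coords -> (energy, gradient)``, with an optional analytic Hessian and a
  central-difference fallback.

Coordinates are always plain real vectors; a 1D system is a length-1 vector
(one code path, no scalar special case).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable

import numpy as np

from .errors import (
    InvalidParameterError,
    SingularConfigurationError,
    UnknownModelError,
)

__all__ = [
    "Configuration",
    "PotentialModel",
    "make_model_potential",
    "potential_value_gradient",
    "potential_hessian",
    "finite_difference_hessian",
]


@dataclasses.dataclass
class Configuration:
    """A point in configuration space, optionally with momenta attached."""

    coordinates: np.ndarray
    momenta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_1d(np.asarray(self.coordinates, dtype=float))
        if self.momenta is not None:
            self.momenta = np.atleast_1d(np.asarray(self.momenta, dtype=float))
            if self.momenta.shape != self.coordinates.shape:
                raise InvalidParameterError("momenta shape must match coordinates")


def _as_coords(x) -> np.ndarray:
    if isinstance(x, Configuration):
        x = x.coordinates
    return np.atleast_1d(np.asarray(x, dtype=float))


class PotentialModel:
    """Base class: energy/gradient/Hessian provider.

    Subclasses must implement :meth:`value` and :meth:`gradient` for a single
    coordinate vector.  1D models additionally expose the element-wise
    ``v/dv/d2v`` helpers, which accept arrays of arbitrary shape and are what
    the vectorized samplers and propagators call.
    """

    name: str = "potential"
    dimension: int = 1
    box_length: float | None = None
    provides_hessian: bool = True

    def __init__(self, params: dict | None = None):
        self.params = dict(params or {})

    # -- single-configuration interface ---------------------------------
    def value(self, x) -> float:
        raise NotImplementedError

    def gradient(self, x) -> np.ndarray:
        raise NotImplementedError

    def value_gradient(self, x) -> tuple[float, np.ndarray]:
        return self.value(x), self.gradient(x)

    def hessian(self, x) -> np.ndarray:
        if not self.provides_hessian:
            raise InvalidParameterError(
                f"{self.name}: no analytic Hessian and finite differencing disabled"
            )
        return finite_difference_hessian(self, _as_coords(x))

    # -- element-wise 1D interface (overridden by 1D models) -------------
    def v(self, x):
        raise NotImplementedError(f"{self.name} has no element-wise 1D form")

    def dv(self, x):
        raise NotImplementedError(f"{self.name} has no element-wise 1D form")

    def d2v(self, x):
        raise NotImplementedError(f"{self.name} has no element-wise 1D form")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<{type(self).__name__} {self.params}>"


class _Model1D(PotentialModel):
    """1D model defined by element-wise v/dv/d2v."""

    dimension = 1

    def value(self, x) -> float:
        (xi,) = _as_coords(x)
        return float(self.v(xi))

    def gradient(self, x) -> np.ndarray:
        (xi,) = _as_coords(x)
        return np.array([self.dv(xi)], dtype=float)

    def hessian(self, x) -> np.ndarray:
        (xi,) = _as_coords(x)
        return np.array([[self.d2v(xi)]], dtype=float)


def _require(params: dict, *names: str) -> list[float]:
    out = []
    for n in names:
        if n not in params:
            raise InvalidParameterError(f"missing required parameter '{n}'")
        val = params[n]
        if not np.all(np.isfinite(val)):
            raise InvalidParameterError(f"parameter '{n}' must be finite, got {val!r}")
        out.append(val)
    return out


class Harmonic(PotentialModel):
    """Uncoupled harmonic oscillators, V = sum_i (1/2) m_i w_i^2 x_i^2.

    ``mass`` and ``omega`` may be scalars (1D) or equal-length sequences.
    """

    name = "harmonic"

    def __init__(self, params: dict):
        super().__init__(params)
        m, w = _require(self.params, "mass", "omega")
        self.m = np.atleast_1d(np.asarray(m, dtype=float))
        self.w = np.atleast_1d(np.asarray(w, dtype=float))
        if self.m.shape != self.w.shape:
            raise InvalidParameterError("mass and omega must have equal length")
        if np.any(self.m <= 0) or np.any(self.w < 0):
            raise InvalidParameterError("mass must be > 0 and omega >= 0")
        self.dimension = self.m.size
        self.k = self.m * self.w**2

    def value(self, x) -> float:
        x = _as_coords(x)
        return float(0.5 * np.sum(self.k * x**2))

    def gradient(self, x) -> np.ndarray:
        return self.k * _as_coords(x)

    def hessian(self, x) -> np.ndarray:
        return np.diag(self.k)

    # 1D element-wise helpers (valid when dimension == 1)
    def v(self, x):
        return 0.5 * self.k[0] * np.asarray(x) ** 2

    def dv(self, x):
        return self.k[0] * np.asarray(x)

    def d2v(self, x):
        return np.full_like(np.asarray(x, dtype=float), self.k[0])


class DoubleWell(_Model1D):
    """Symmetric quartic double well V = -a x^2/2 + b x^4/4 (a, b > 0).

    Minima at +-sqrt(a/b), barrier height a^2/(4b) at x = 0.
    """

    name = "double_well"

    def __init__(self, params: dict):
        super().__init__(params)
        a, b = _require(self.params, "a", "b")
        if a <= 0 or b <= 0:
            raise InvalidParameterError("double_well requires a > 0 and b > 0")
        self.a, self.b = float(a), float(b)

    def v(self, x):
        x = np.asarray(x)
        return -0.5 * self.a * x**2 + 0.25 * self.b * x**4

    def dv(self, x):
        x = np.asarray(x)
        return -self.a * x + self.b * x**3

    def d2v(self, x):
        x = np.asarray(x)
        return -self.a + 3.0 * self.b * x**2

    @property
    def minima(self) -> np.ndarray:
        r = math.sqrt(self.a / self.b)
        return np.array([-r, r])


class Quartic(_Model1D):
    """Pure quartic oscillator V = c x^4 / 4."""

    name = "quartic"

    def __init__(self, params: dict):
        super().__init__(params)
        (c,) = _require(self.params, "c")
        if c <= 0:
            raise InvalidParameterError("quartic requires c > 0")
        self.c = float(c)

    def v(self, x):
        return 0.25 * self.c * np.asarray(x) ** 4

    def dv(self, x):
        return self.c * np.asarray(x) ** 3

    def d2v(self, x):
        return 3.0 * self.c * np.asarray(x) ** 2


class Morse(_Model1D):
    """Morse oscillator V = D (1 - exp(-a(x-x0)))^2."""

    name = "morse"

    def __init__(self, params: dict):
        super().__init__(params)
        D, a = _require(self.params, "D", "a")
        x0 = float(self.params.get("x0", 0.0))
        if D <= 0 or a <= 0:
            raise InvalidParameterError("morse requires D > 0 and a > 0")
        self.D, self.a, self.x0 = float(D), float(a), x0

    def v(self, x):
        e = np.exp(-self.a * (np.asarray(x) - self.x0))
        return self.D * (1.0 - e) ** 2

    def dv(self, x):
        e = np.exp(-self.a * (np.asarray(x) - self.x0))
        return 2.0 * self.D * self.a * (1.0 - e) * e

    def d2v(self, x):
        e = np.exp(-self.a * (np.asarray(x) - self.x0))
        return 2.0 * self.D * self.a**2 * (2.0 * e**2 - e)


class ParabolicBarrier(_Model1D):
    """Inverted parabola V = -(1/2) m wb^2 x^2 (a barrier of curvature -m wb^2)."""

    name = "parabolic_barrier"

    def __init__(self, params: dict):
        super().__init__(params)
        m, wb = _require(self.params, "mass", "omega_b")
        if m <= 0 or wb <= 0:
            raise InvalidParameterError("parabolic_barrier requires mass, omega_b > 0")
        self.k = float(m) * float(wb) ** 2

    def v(self, x):
        return -0.5 * self.k * np.asarray(x) ** 2

    def dv(self, x):
        return -self.k * np.asarray(x)

    def d2v(self, x):
        return np.full_like(np.asarray(x, dtype=float), -self.k)


class PairLiquidLJ(PotentialModel):
    """Periodic 1D chain of particles with a truncated + shifted
    Lennard-Jones pair interaction under the minimum-image convention.

    The pair potential u(r) = 4 eps [(sig/r)^12 - (sig/r)^6] is cut at half
    the box length and shifted so u(rc) = 0, keeping forces finite and the
    dynamics conservative.  Below r_core = 0.6 sigma the potential is
    continued quadratically (matching u, u', u'' at r_core): the Gaussian
    smearing of a bare r^-12 core is a divergent integral, and the
    regularized core is never visited at the thermal states of interest.
    """

    name = "pair_liquid"

    def __init__(self, params: dict):
        super().__init__(params)
        n, L, eps, sig = _require(
            self.params, "n_particles", "box_length", "epsilon", "sigma"
        )
        self.mass = float(self.params.get("mass", 1.0))
        n = int(n)
        if n < 2:
            raise InvalidParameterError("pair_liquid needs at least 2 particles")
        if L <= 0:
            raise InvalidParameterError("box_length must be positive")
        if eps <= 0 or sig <= 0:
            raise InvalidParameterError("epsilon and sigma must be positive")
        self.dimension = n
        self.n = n
        self.box_length = float(L)
        self.eps, self.sig = float(eps), float(sig)
        self.rc = 0.5 * self.box_length
        sr6 = (self.sig / self.rc) ** 6
        self.ushift = 4.0 * self.eps * (sr6**2 - sr6)
        self.r_core = 0.6 * self.sig
        s6 = (self.sig / self.r_core) ** 6
        self._u0 = 4.0 * self.eps * (s6**2 - s6) - self.ushift
        self._du0 = 4.0 * self.eps * (-12.0 * s6**2 + 6.0 * s6) / self.r_core
        self._d2u0 = 4.0 * self.eps * (156.0 * s6**2 - 42.0 * s6) / self.r_core**2

    # pair terms --------------------------------------------------------
    def _u(self, r):
        rs = np.maximum(r, self.r_core)
        sr6 = (self.sig / rs) ** 6
        lj = 4.0 * self.eps * (sr6**2 - sr6) - self.ushift
        d = np.where(r < self.r_core, r - self.r_core, 0.0)
        core = self._u0 + self._du0 * d + 0.5 * self._d2u0 * d**2
        return np.where(r < self.rc, np.where(r < self.r_core, core, lj), 0.0)

    def _du(self, r):
        rs = np.maximum(r, self.r_core)
        sr6 = (self.sig / rs) ** 6
        lj = 4.0 * self.eps * (-12.0 * sr6**2 + 6.0 * sr6) / rs
        core = self._du0 + self._d2u0 * np.where(r < self.r_core,
                                                 r - self.r_core, 0.0)
        return np.where(r < self.rc, np.where(r < self.r_core, core, lj), 0.0)

    def _d2u(self, r):
        rs = np.maximum(r, self.r_core)
        sr6 = (self.sig / rs) ** 6
        lj = 4.0 * self.eps * (156.0 * sr6**2 - 42.0 * sr6) / rs**2
        return np.where(
            r < self.rc,
            np.where(r < self.r_core, self._d2u0, lj),
            0.0,
        )

    def minimum_image(self, dx):
        L = self.box_length
        return dx - L * np.round(dx / L)

    def _pair_table(self, x: np.ndarray):
        """Signed min-image separations and distances for i<j pairs."""
        iu, ju = np.triu_indices(self.n, k=1)
        dx = self.minimum_image(x[iu] - x[ju])
        r = np.abs(dx)
        if np.any(r < 1e-10 * self.sig):
            raise SingularConfigurationError("overlapping particles in pair_liquid")
        return iu, ju, dx, r

    def value(self, x) -> float:
        x = _as_coords(x)
        _, _, _, r = self._pair_table(x)
        e = float(np.sum(self._u(r)))
        if not np.isfinite(e):
            raise SingularConfigurationError("non-finite pair energy")
        return e

    def gradient(self, x) -> np.ndarray:
        x = _as_coords(x)
        iu, ju, dx, r = self._pair_table(x)
        # dV/dx_i = sum_j u'(r_ij) * sign(x_i - x_j)
        f = self._du(r) * np.sign(dx)
        g = np.zeros(self.n)
        np.add.at(g, iu, f)
        np.add.at(g, ju, -f)
        if not np.all(np.isfinite(g)):
            raise SingularConfigurationError("non-finite pair forces")
        return g

    def hessian(self, x) -> np.ndarray:
        x = _as_coords(x)
        iu, ju, dx, r = self._pair_table(x)
        d2 = self._d2u(r)
        H = np.zeros((self.n, self.n))
        for i, j, h in zip(iu, ju, d2):
            H[i, i] += h
            H[j, j] += h
            H[i, j] -= h
            H[j, i] -= h
        return H

    # vectorized ensemble forces for the propagators --------------------
    def forces_batch(self, X: np.ndarray) -> np.ndarray:
        """Forces (-gradient) for a batch of configurations, shape (m, n)."""
        X = np.asarray(X, dtype=float)
        dx = self.minimum_image(X[:, :, None] - X[:, None, :])
        r = np.abs(dx)
        np.fill_diagonal(r[0].reshape(-1, self.n, self.n)[0], np.inf)
        # fill all diagonals
        idx = np.arange(self.n)
        r[:, idx, idx] = np.inf
        du = self._du(r)
        f = -np.sum(du * np.sign(dx), axis=2)
        return f

    def hessians_batch(self, X: np.ndarray) -> np.ndarray:
        """Hessians for a batch of configurations, shape (m, n, n)."""
        X = np.asarray(X, dtype=float)
        m = X.shape[0]
        dx = self.minimum_image(X[:, :, None] - X[:, None, :])
        r = np.abs(dx)
        idx = np.arange(self.n)
        r[:, idx, idx] = np.inf
        d2 = self._d2u(r)  # zero on the (r = inf) diagonal
        H = -d2
        H[:, idx, idx] = np.sum(d2, axis=2)
        return H

    def energies_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        dx = self.minimum_image(X[:, :, None] - X[:, None, :])
        r = np.abs(dx)
        idx = np.arange(self.n)
        r[:, idx, idx] = np.inf
        return 0.5 * np.sum(self._u(r), axis=(1, 2))


class ExternalPotential(PotentialModel):
    """Wraps a user force routine: a pure function coords -> (energy, gradient).

    An analytic Hessian callable may be supplied; otherwise a central
    finite-difference Hessian is used when ``allow_fd_hessian`` is true.
    """

    name = "external"

    def __init__(self, params: dict):
        super().__init__(params)
        func = self.params.get("func")
        if not callable(func):
            raise InvalidParameterError("external requires a callable 'func'")
        self.func: Callable = func
        self.dimension = int(self.params.get("dimension", 1))
        self.hessian_func = self.params.get("hessian_func")
        self.allow_fd_hessian = bool(self.params.get("allow_fd_hessian", True))
        self.provides_hessian = self.hessian_func is not None or self.allow_fd_hessian

    def value(self, x) -> float:
        e, _ = self.func(_as_coords(x))
        return float(e)

    def gradient(self, x) -> np.ndarray:
        _, g = self.func(_as_coords(x))
        return np.asarray(g, dtype=float)

    def value_gradient(self, x):
        e, g = self.func(_as_coords(x))
        return float(e), np.asarray(g, dtype=float)

    def hessian(self, x) -> np.ndarray:
        if self.hessian_func is not None:
            return np.asarray(self.hessian_func(_as_coords(x)), dtype=float)
        if not self.allow_fd_hessian:
            raise InvalidParameterError(
                "external: no analytic Hessian and finite differencing disabled"
            )
        return finite_difference_hessian(self, _as_coords(x))

    # element-wise 1D helpers via the wrapped routine
    def v(self, x):
        x = np.asarray(x, dtype=float)
        flat = np.atleast_1d(x).ravel()
        out = np.array([self.func(np.array([xi]))[0] for xi in flat])
        return out.reshape(np.shape(x)) if np.shape(x) else out[0]

    def dv(self, x):
        x = np.asarray(x, dtype=float)
        flat = np.atleast_1d(x).ravel()
        out = np.array([self.func(np.array([xi]))[1][0] for xi in flat])
        return out.reshape(np.shape(x)) if np.shape(x) else out[0]

    def d2v(self, x):
        x = np.asarray(x, dtype=float)
        flat = np.atleast_1d(x).ravel()
        out = np.array([self.hessian(np.array([xi]))[0, 0] for xi in flat])
        return out.reshape(np.shape(x)) if np.shape(x) else out[0]


_REGISTRY = {
    "harmonic": Harmonic,
    "double_well": DoubleWell,
    "quartic": Quartic,
    "morse": Morse,
    "parabolic_barrier": ParabolicBarrier,
    "pair_liquid": PairLiquidLJ,
    "external": ExternalPotential,
}


def make_model_potential(name: str, params: dict | None = None) -> PotentialModel:
    """Instantiate a registered potential model by name."""
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise UnknownModelError(
            f"unknown model '{name}'; known: {sorted(_REGISTRY)}"
        ) from None
    return cls(dict(params or {}))


def potential_value_gradient(model: PotentialModel, config) -> tuple[float, np.ndarray]:
    """Energy and gradient for one configuration, with dimension checks."""
    x = _as_coords(config)
    if x.size != model.dimension:
        raise InvalidParameterError(
            f"configuration length {x.size} != model dimension {model.dimension}"
        )
    e, g = model.value_gradient(x)
    if not (np.isfinite(e) and np.all(np.isfinite(g))):
        raise SingularConfigurationError("non-finite energy or gradient")
    return e, g


def potential_hessian(model: PotentialModel, config) -> np.ndarray:
    """Symmetrized Hessian for one configuration."""
    x = _as_coords(config)
    if x.size != model.dimension:
        raise InvalidParameterError(
            f"configuration length {x.size} != model dimension {model.dimension}"
        )
    H = model.hessian(x)
    return 0.5 * (H + H.T)


def finite_difference_hessian(
    model: PotentialModel, x: np.ndarray, step: float | None = None
) -> np.ndarray:
    """Central-difference Hessian from gradient calls.

    Default step is 1e-5 * max(1, |x_i|) per coordinate.
    """
    x = _as_coords(x)
    n = x.size
    H = np.zeros((n, n))
    for i in range(n):
        h = step if step is not None else 1e-5 * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        gp = np.asarray(model.gradient(xp), dtype=float)
        gm = np.asarray(model.gradient(xm), dtype=float)
        H[i] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)
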