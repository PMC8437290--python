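"""Characteristic function, dominant root and eigenpairs of the GBM model.

For the geometric-Brownian-motion / allometric-fertility life history the
renewal (Euler-Lotka) condition has a rational characteristic function.
Writing ``D(r) = r + mu0 - rho*b1 + 0.5*sigma1**2*rho*(1-rho)`` for the
discount net of the growth of the fertility moment,

    psi(r) = f0 * x**rho / D(r),

which is strictly decreasing on ``(pole, inf)`` with a single simple pole at
``pole = rho*(b1 - sigma1**2*(1-rho)/2) - mu0``.  The unique real root of
``psi(r) = 1`` is therefore

    r0 = rho*(b1 - sigma1**2*(1-rho)/2) + f0*x**rho - mu0 = pole + f0*x**rho.

The associated eigenfunction ``w0(a, y)`` is the lognormal transition
density of the size process times the discount ``exp(-(mu0+r0)a)``, and the
reproductive value (adjoint eigenfunction) is ``v0(y) = f0*y**rho`` — it
coincides with the fertility function, normalized so that the duality
pairing <v0, w0> equals one.

Each closed form here is backed by an independent numerical route (root
bracketing, quadrature, Feynman-Kac Monte Carlo) used by the test suite as
an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateInputError, DivergenceError, ParameterError
from .params import GBMAllometricParams

__all__ = [
    "CharacteristicRoot",
    "Eigenpair",
    "ValueEstimate",
    "convergence_abscissa",
    "psi",
    "psi_quadrature",
    "dominant_root",
    "dominant_root_numeric",
    "reproduction_number",
    "eigenfunction_w",
    "reproductive_value",
    "feynman_kac_value_mc",
    "pairing",
    "eigenpair",
]


# --------------------------------------------------------------------------
# Characteristic function and roots
# --------------------------------------------------------------------------

def convergence_abscissa(params: GBMAllometricParams) -> float:
    """Abscissa below which the discounted-fertility age integral diverges."""
    return (
        params.rho * (params.b1 - 0.5 * params.sigma1**2 * (1.0 - params.rho))
        - params.mu0
    )


@dataclass(frozen=True)
class CharacteristicRoot:
    """Dominant characteristic root together with the convergence abscissa."""

    r0: float
    pole: float

    def __post_init__(self) -> None:
        if not self.r0 > self.pole:
            raise DivergenceError(
                f"characteristic root r0={self.r0} not above the pole {self.pole}"
            )


def psi(r: float, params: GBMAllometricParams) -> float:
    """Characteristic-function value (closed rational form).

    Raises :class:`DivergenceError` for ``r <= pole`` where the defining age
    integral diverges.
    """
    pole = convergence_abscissa(params)
    if r <= pole:
        raise DivergenceError(
            f"psi diverges for r={r} <= convergence abscissa {pole}"
        )
    return params.fertility_at_birth / (r - pole)


def _expected_fertility(a, r, params: GBMAllometricParams) -> np.ndarray:
    """exp(-r a) * E_x[f0 X_a^rho] * exp(-mu0 a), via the exact GBM moment."""
    p = params
    growth = p.rho * p.b1 - 0.5 * p.sigma1**2 * p.rho * (1.0 - p.rho)
    return p.fertility_at_birth * np.exp((growth - p.mu0 - r) * np.asarray(a))


def psi_quadrature(
    r: float,
    params: GBMAllometricParams,
    *,
    use_transition_density: bool = True,
    n_size_nodes: int = 200,
) -> float:
    """Characteristic function by numerical quadrature (independent oracle).

    Integrates ``exp(-r a) * f0 * E_x[X_a^rho] * exp(-mu0 a)`` over age.
    With ``use_transition_density`` the inner expectation is itself computed
    by Gauss-Legendre quadrature in log size against the lognormal
    transition density (requires ``sigma1 > 0``); otherwise the exact GBM
    moment is used.  Ages are integrated panel by panel, doubling the upper
    limit until the last panel contributes < 1e-10 of the running total.
    """
    pole = convergence_abscissa(params)
    if r <= pole:
        raise DivergenceError(
            f"psi diverges for r={r} <= convergence abscissa {pole}"
        )
    if use_transition_density and params.sigma1 == 0.0:
        raise DegenerateInputError(
            "sigma1=0: transition density degenerate; "
            "use use_transition_density=False"
        )

    if use_transition_density:
        def inner(a_vec: np.ndarray) -> np.ndarray:
            out = np.empty_like(a_vec)
            for i, a in enumerate(a_vec):
                out[i] = math.exp(-r * a) * _size_integral(
                    a, params, lambda y: params.f0 * y**params.rho, n_size_nodes
                ) * math.exp(-params.mu0 * a)
            return out
    else:
        def inner(a_vec: np.ndarray) -> np.ndarray:
            return _expected_fertility(a_vec, r, params)

    return _age_integral(inner)


def dominant_root(params: GBMAllometricParams) -> CharacteristicRoot:
    """Dominant characteristic root, in closed form."""
    pole = convergence_abscissa(params)
    return CharacteristicRoot(r0=pole + params.fertility_at_birth, pole=pole)


def dominant_root_numeric(
    params: GBMAllometricParams, *, xtol: float = 1e-14
) -> float:
    """Root of ``psi(r) = 1`` by bracketed root finding (independent oracle).

    The bracket starts at ``[pole + 1e-6, pole + 1]``; the upper bound is
    doubled (in distance from the pole) until ``psi < 1`` there, which is
    guaranteed to terminate because ``psi`` is strictly decreasing to zero.
    """
    pole = convergence_abscissa(params)
    lo = pole + 1e-6
    hi = pole + 1.0
    while psi(hi, params) > 1.0:
        hi = pole + 2.0 * (hi - pole)
    if psi(lo, params) < 1.0:
        # The root sits within 1e-6 of the pole; shrink the lower bracket.
        while psi(lo, params) < 1.0:
            lo = pole + 0.5 * (lo - pole)
    return float(
        optimize.brentq(lambda r: psi(r, params) - 1.0, lo, hi, xtol=xtol)
    )


def reproduction_number(params: GBMAllometricParams) -> float:
    """Expected lifetime reproductive output R0 (= psi at r = 0).

    Defined only when the convergence abscissa is negative; otherwise the
    lifetime reproduction integral diverges.
    """
    pole = convergence_abscissa(params)
    if pole >= 0.0:
        raise DivergenceError(
            "R0 undefined: lifetime reproduction integral diverges "
            f"(convergence abscissa {pole} >= 0)"
        )
    return params.fertility_at_birth / (-pole)


# --------------------------------------------------------------------------
# Eigenfunctions
# --------------------------------------------------------------------------

def eigenfunction_w(a, y, r: float, params: GBMAllometricParams):
    """Eigenfunction value: lognormal transition density times the discount.

    ``w_r(a, y)`` is the density (in size) of a GBM started at the neonate
    size, multiplied by ``exp(-(mu0 + r) a)``; its size integral at age
    ``a`` is exactly ``exp(-(mu0 + r) a)``.  The ``a = 0`` point mass is not
    evaluated pointwise.
    """
    if params.sigma1 == 0.0:
        raise DegenerateInputError(
            "sigma1=0: size distribution is a point mass; "
            "eigenfunction has no density"
        )
    a = np.asarray(a, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(a <= 0.0):
        raise ParameterError("age must be positive (a=0 is a point mass at x)")
    if np.any(y <= 0.0):
        raise ParameterError("size must be positive")
    m = math.log(params.x) + (params.b1 - 0.5 * params.sigma1**2) * a
    s = params.sigma1 * np.sqrt(a)
    dens = np.exp(-0.5 * ((np.log(y) - m) / s) ** 2) / (y * s * math.sqrt(2.0 * math.pi))
    return dens * np.exp(-(params.mu0 + r) * a)


def reproductive_value(y, params: GBMAllometricParams):
    """Reproductive value v0(y) = f0 * y**rho (matches the fertility function)."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0.0):
        raise ParameterError("size must be positive")
    return params.f0 * y**params.rho


@dataclass(frozen=True)
class Eigenpair:
    """Dominant eigenpair with its duality pairing (normalized to one)."""

    root: CharacteristicRoot
    w0: Callable
    v0: Callable
    pairing: float


def eigenpair(params: GBMAllometricParams, *, check: bool = True) -> Eigenpair:
    """Build the dominant eigenpair; optionally verify <v0, w0> = 1."""
    root = dominant_root(params)

    def w0(a, y):
        return eigenfunction_w(a, y, root.r0, params)

    def v0(y):
        return reproductive_value(y, params)

    val = 1.0
    if check:
        val = pairing(lambda a, y: v0(y), w0, params)
    return Eigenpair(root=root, w0=w0, v0=v0, pairing=val)


# --------------------------------------------------------------------------
# Quadrature helpers
# --------------------------------------------------------------------------

_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gl_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _GL_CACHE:
        _GL_CACHE[n] = np.polynomial.legendre.leggauss(n)
    return _GL_CACHE[n]


def _size_integral(a: float, params: GBMAllometricParams, fn, n_nodes: int) -> float:
    """Integrate fn(y) * transition_density(a, y) dy in log-size coordinates.

    The integrand is Gaussian in z = ln y; limits are set at +-10 standard
    deviations around the log mean.
    """
    m = math.log(params.x) + (params.b1 - 0.5 * params.sigma1**2) * a
    s = params.sigma1 * math.sqrt(a)
    z_nodes, z_weights = _gl_nodes(n_nodes)
    z = m + 10.0 * s * z_nodes
    w = 10.0 * s * z_weights
    dens = np.exp(-0.5 * ((z - m) / s) ** 2) / (s * math.sqrt(2.0 * math.pi))
    return float(np.sum(w * dens * fn(np.exp(z))))


def _age_integral(
    inner,
    *,
    a_start: float = 0.0,
    first_panel: float = 1.0,
    rel_tail: float = 1e-10,
    max_doublings: int = 60,
    n_nodes: int = 64,
    sqrt_substitution: bool = False,
) -> float:
    """Adaptive panel integral of ``inner(a)`` over [a_start, inf).

    Panels double in width; integration stops once the last panel
    contributes less than ``rel_tail`` of the running total.  With
    ``sqrt_substitution`` the first panel is computed in s = sqrt(a)
    coordinates, which removes integrable 1/sqrt(a) behavior at zero.
    """
    nodes, weights = _gl_nodes(n_nodes)
    total = 0.0
    lo = a_start
    width = first_panel
    for k in range(max_doublings):
        hi = lo + width
        if k == 0 and sqrt_substitution and a_start == 0.0:
            s_lo, s_hi = 0.0, math.sqrt(hi)
            mid, half = 0.5 * (s_lo + s_hi), 0.5 * (s_hi - s_lo)
            s = mid + half * nodes
            contrib = float(np.sum(half * weights * 2.0 * s * inner(s**2)))
        else:
            mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
            a = mid + half * nodes
            contrib = float(np.sum(half * weights * inner(a)))
        total += contrib
        if not math.isfinite(contrib):
            raise DivergenceError("age integral produced a non-finite panel")
        if k >= 2 and abs(contrib) < rel_tail * max(abs(total), 1e-300):
            return total
        lo = hi
        width *= 2.0
    raise DivergenceError(
        "age integral did not decay: integrand appears non-integrable "
        "(convergence abscissa violated?)"
    )


def pairing(
    v_fn,
    w_fn,
    params: GBMAllometricParams,
    age_cap: Optional[float] = None,
    *,
    n_size_nodes: int = 200,
) -> float:
    """Duality pairing <v, w> = int da int dy v(a,y) w(a,y).

    The size integral is performed in log-size coordinates on a window of
    +-10 standard deviations of the model's transition kernel at each age;
    the age integral extends adaptively (panel doubling) until the relative
    tail is below 1e-10, or up to ``age_cap`` if given.  A non-decaying
    integrand raises :class:`DivergenceError`.
    """
    if params.sigma1 == 0.0:
        raise DegenerateInputError("sigma1=0: pairing quadrature needs a density")

    def inner(a_vec: np.ndarray) -> np.ndarray:
        out = np.empty_like(a_vec)
        for i, a in enumerate(a_vec):
            m = math.log(params.x) + (params.b1 - 0.5 * params.sigma1**2) * a
            s = params.sigma1 * math.sqrt(a)
            z_nodes, z_weights = _gl_nodes(n_size_nodes)
            # keep exp(z) inside double range; the clipped tail carries a
            # Gaussian weight below e^-50 and is negligible
            z = np.clip(m + 10.0 * s * z_nodes, -700.0, 700.0)
            y = np.exp(z)
            with np.errstate(over="ignore", invalid="ignore"):
                vals = 10.0 * s * z_weights * y * v_fn(a, y) * w_fn(a, y)
            out[i] = float(np.sum(np.nan_to_num(vals, nan=0.0,
                                                posinf=0.0, neginf=0.0)))
        return out

    if age_cap is not None:
        nodes, weights = _gl_nodes(256)
        mid, half = 0.5 * age_cap, 0.5 * age_cap
        a = mid + half * nodes
        return float(np.sum(half * weights * inner(a)))
    return _age_integral(inner, first_panel=1.0, sqrt_substitution=True)


# --------------------------------------------------------------------------
# Feynman-Kac Monte Carlo oracle
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ValueEstimate:
    """A Monte Carlo estimate with its standard error and provenance."""

    mean: float
    stderr: float
    n_paths: int
    seed: int

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.mean - 1.96 * self.stderr, self.mean + 1.96 * self.stderr)


def feynman_kac_value_mc(
    y: float,
    r: float,
    params: GBMAllometricParams,
    n_paths: int = 2000,
    horizon: Optional[float] = None,
    seed: int = 0,
    *,
    dt: float = 0.01,
) -> ValueEstimate:
    """Monte Carlo of the discounted expected-fertility integral.

    Estimates ``int_0^inf exp(-(r+mu0)s) E_y[f0 X_s^rho] ds`` by simulating
    exact GBM paths on a uniform grid and applying the trapezoidal rule.
    The closed form is ``f0 y^rho / (r - pole)``; at ``r = r0`` and
    ``y = x`` this is the characteristic identity psi(r0) = 1.

    The horizon is chosen so the truncated exponential tail is below 1e-7
    of the estimate.  With ``sigma1 = 0`` the paths are deterministic and
    the result is a pure quadrature (stderr = 0).
    """
    pole = convergence_abscissa(params)
    if r <= pole:
        raise DivergenceError(
            f"Feynman-Kac integral diverges for r={r} <= abscissa {pole}"
        )
    decay = r - pole  # decay rate of the integrand's expectation
    if horizon is None:
        horizon = math.log(1e7) / decay
    n_steps = max(int(math.ceil(horizon / dt)), 32)
    tgrid = np.linspace(0.0, horizon, n_steps + 1)
    step = tgrid[1] - tgrid[0]

    p = params
    if p.sigma1 == 0.0:
        path_moment = p.f0 * y**p.rho * np.exp(p.rho * p.b1 * tgrid)
        integrand = np.exp(-(r + p.mu0) * tgrid) * path_moment
        val = float(np.trapezoid(integrand, dx=step))
        return ValueEstimate(mean=val, stderr=0.0, n_paths=0, seed=seed)

    rng = np.random.default_rng(seed)
    # exact GBM log increments
    drift = (p.b1 - 0.5 * p.sigma1**2) * step
    vol = p.sigma1 * math.sqrt(step)
    logx = np.full(n_paths, math.log(y))
    disc = np.exp(-(r + p.mu0) * tgrid)
    acc = np.zeros(n_paths)
    prev = disc[0] * p.f0 * np.exp(p.rho * logx)
    for i in range(1, n_steps + 1):
        logx += drift + vol * rng.standard_normal(n_paths)
        cur = disc[i] * p.f0 * np.exp(p.rho * logx)
        acc += 0.5 * step * (prev + cur)
        prev = cur
    mean = float(np.mean(acc))
    stderr = float(np.std(acc, ddof=1) / math.sqrt(n_paths))
    return ValueEstimate(mean=mean, stderr=stderr, n_paths=n_paths, seed=seed)
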