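"""Parameter bundles and shared coefficient algebra.

The solvable life-history model couples three ingredients:

* geometric-Brownian-motion (GBM) size growth
  ``dX = b1 X da + sigma1 X dB``, started at the neonate size ``x``;
* a constant force of mortality ``mu0``;
* allometric fertility ``F(y) = f0 * y**rho`` with ``0 < rho < 1``.

The two-resource variant mixes a risky resource (``b1``, ``sigma1``) with a
safe one (``b2``, ``sigma2``) through a constant utilization fraction
``u`` in [0, 1]: ``u`` is the weight on the safe resource R2.  Because the
two Brownian drivers are independent, a constant-``u`` mixture is again a
GBM with effective coefficients

    b_eff(u)  = b1*(1-u) + b2*u
    s2_eff(u) = sigma1**2*(1-u)**2 + sigma2**2*u**2

so every two-resource computation reduces to the single-resource machinery
via :func:`as_gbm`.

All bundles are frozen dataclasses validated on construction; downstream
modules only ever see validated bundles.  Units are abstract "per unit
time"; no unit conversion is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

from .errors import ParameterError

__all__ = [
    "GBMAllometricParams",
    "TwoResourceParams",
    "EnvironmentSpec",
    "GenericLifeHistory",
    "validate",
    "effective_coefficients",
    "as_gbm",
]


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ParameterError(message)


@dataclass(frozen=True)
class GBMAllometricParams:
    """Parameters of the GBM / allometric-fertility life history.

    Attributes
    ----------
    b1 : float
        Mean size growth rate (per unit time).
    sigma1 : float
        Size-growth volatility (per sqrt time), >= 0.  ``sigma1 = 0`` is the
        deterministic limit; operations whose formulas divide by ``sigma1``
        raise :class:`~stochlife.errors.DegenerateInputError` for it.
    x : float
        Neonate size, > 0.  All neonates are born at this size (the neonate
        state distribution is a point mass at ``x``).
    mu0 : float
        Constant force of mortality (per unit time), >= 0.
    f0 : float
        Fertility coefficient (births per unit time per size**rho), > 0.
    rho : float
        Allometric fertility exponent, strictly inside (0, 1).
    """

    b1: float
    sigma1: float
    x: float
    mu0: float
    f0: float
    rho: float

    def __post_init__(self) -> None:
        _require(0.0 < self.rho < 1.0, f"rho out of range (0,1): rho={self.rho}")
        _require(self.x > 0.0, f"x must be positive: x={self.x}")
        _require(self.f0 > 0.0, f"f0 must be positive: f0={self.f0}")
        _require(self.sigma1 >= 0.0, f"sigma1 must be >= 0: sigma1={self.sigma1}")
        _require(self.mu0 >= 0.0, f"mu0 must be >= 0: mu0={self.mu0}")
        for name in ("b1", "sigma1", "x", "mu0", "f0", "rho"):
            _require(math.isfinite(getattr(self, name)), f"{name} must be finite")

    # Convenience shared by the spectral/perturbation algebra ------------

    @property
    def fertility_at_birth(self) -> float:
        """f0 * x**rho — the per-capita birth rate of a neonate."""
        return self.f0 * self.x**self.rho

    def with_sigma1(self, sigma1: float) -> "GBMAllometricParams":
        return replace(self, sigma1=sigma1)


@dataclass(frozen=True)
class TwoResourceParams:
    """Two-resource utilization model parameters.

    Resource R1 is risky (high mean growth ``b1``, high volatility
    ``sigma1``); R2 is safe (``b2 <= b1``, ``sigma2 < sigma1``).  ``b2`` may
    be negative.  The demographic fields (``x``, ``mu0``, ``f0``, ``rho``)
    are shared with :class:`GBMAllometricParams`.
    """

    b1: float
    b2: float
    sigma1: float
    sigma2: float
    x: float
    mu0: float
    f0: float
    rho: float

    def __post_init__(self) -> None:
        # Validate the shared demographic block with the same rules.
        GBMAllometricParams(self.b1, self.sigma1, self.x, self.mu0, self.f0, self.rho)
        _require(math.isfinite(self.b2), "b2 must be finite")
        _require(math.isfinite(self.sigma2), "sigma2 must be finite")
        if self.b1 < self.b2:
            raise ParameterError(f"resource ordering violated: b1={self.b1} < b2={self.b2}")
        if not (self.sigma1 > self.sigma2 >= 0.0):
            raise ParameterError(
                f"volatility ordering violated: need sigma1 > sigma2 >= 0, "
                f"got sigma1={self.sigma1}, sigma2={self.sigma2}"
            )


@dataclass(frozen=True)
class EnvironmentSpec:
    """External-noise amplitude.

    ``epsilon`` multiplies a space-time white-noise field perturbing the
    population operator.  The second-order growth-rate approximation is
    documented as valid for small ``epsilon``.
    """

    epsilon: float = 0.0

    def __post_init__(self) -> None:
        _require(self.epsilon >= 0.0, f"epsilon must be >= 0: epsilon={self.epsilon}")
        _require(math.isfinite(self.epsilon), "epsilon must be finite")


@dataclass(frozen=True)
class GenericLifeHistory:
    """A general age-by-size life history given by rate functions.

    ``drift``, ``diffusion``, ``mortality`` and ``fertility`` are callables
    of ``(age, size)``.  ``diffusion`` is a variance rate and must be
    nonnegative, as must the hazard and the birth rate.  For a finite
    ``max_age`` the cumulative hazard must diverge at ``max_age`` (nobody
    survives past the maximum age); this cannot be certified numerically in
    general and is spot-checked on a sample grid by :meth:`spot_check`.
    """

    drift: Callable[[float, float], float]
    diffusion: Callable[[float, float], float]
    mortality: Callable[[float, float], float]
    fertility: Callable[[float, float], float]
    neonate_size: float
    max_age: float = math.inf

    def __post_init__(self) -> None:
        _require(self.neonate_size > 0.0, "neonate_size must be positive")
        _require(self.max_age > 0.0, "max_age must be positive")

    def spot_check(self, ages, sizes) -> None:
        """Verify sign invariants on a sample grid; raises ParameterError."""
        for a in ages:
            for y in sizes:
                if self.diffusion(a, y) < 0.0:
                    raise ParameterError(f"diffusion negative at (a={a}, y={y})")
                if self.mortality(a, y) < 0.0:
                    raise ParameterError(f"mortality negative at (a={a}, y={y})")
                if self.fertility(a, y) < 0.0:
                    raise ParameterError(f"fertility negative at (a={a}, y={y})")

    @classmethod
    def from_gbm(cls, params: GBMAllometricParams) -> "GenericLifeHistory":
        return cls(
            drift=lambda a, y: params.b1 * y,
            diffusion=lambda a, y: (params.sigma1 * y) ** 2,
            mortality=lambda a, y: params.mu0,
            fertility=lambda a, y: params.f0 * y**params.rho,
            neonate_size=params.x,
            max_age=math.inf,
        )


def validate(params):
    """Return ``params`` unchanged if all invariants hold.

    Validation happens on construction for the dataclass bundles, so this is
    mostly a re-assertion hook for bundles that crossed a serialization
    boundary; it re-runs ``__post_init__`` checks.
    """
    if isinstance(params, (GBMAllometricParams, TwoResourceParams, EnvironmentSpec)):
        params.__post_init__()
        return params
    raise ParameterError(f"unsupported parameter bundle: {type(params).__name__}")


def effective_coefficients(params: TwoResourceParams, u: float) -> tuple[float, float]:
    """Effective (growth rate, variance rate) of the u-mixed resource model.

    With independent drivers, the mixture ``(1-u)·R1 + u·R2`` is a GBM with
    drift ``b1(1-u) + b2 u`` and variance rate ``sigma1²(1-u)² + sigma2²u²``.
    """
    if not 0.0 <= u <= 1.0:
        raise ParameterError(f"utilization fraction outside [0,1]: u={u}")
    b_eff = params.b1 * (1.0 - u) + params.b2 * u
    s2_eff = params.sigma1**2 * (1.0 - u) ** 2 + params.sigma2**2 * u**2
    return b_eff, s2_eff


def as_gbm(params: TwoResourceParams, u: float) -> GBMAllometricParams:
    """Package the u-mixed coefficients with the shared demographic fields."""
    b_eff, s2_eff = effective_coefficients(params, u)
    return GBMAllometricParams(
        b1=b_eff,
        sigma1=math.sqrt(s2_eff),
        x=params.x,
        mu0=params.mu0,
        f0=params.f0,
        rho=params.rho,
    )
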