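"""Temperature-scaled stochastic logistic model: parameterizations and closed forms.

The population model is a density-dependent birth--death process on
``0 <= n <= N`` with per-capita birth rate ``theta1 * (1 - theta2 * n / N)``
and per-capita death rate ``theta3``.  Its mean obeys the logistic equation
with maximum growth rate ``r = theta1 - theta3`` and carrying capacity
``K = N * (theta1 - theta3) / (theta1 * theta2)``.  Temperature enters through
the Arrhenius law applied to each rate parameter:

    theta_i(T) = theta_i(T0) * exp(-(E_A,i / kB) * (1/T - 1/T0))

so that, when all three activation energies are equal, ``log r(T)`` is linear
in ``1/(kB*T)`` with slope ``-E_A`` and ``log K(T)`` is linear with slope
``+E_A``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KB",
    "T0_DEFAULT",
    "BDPParams",
    "ArrheniusModel",
    "LogisticParams",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "arrhenius_scale",
    "derive_logistic",
    "logistic_mean",
    "scale_model",
]

#: Boltzmann constant in eV/K (CODATA). Single source of truth for the package.
KB: float = 8.617333262e-5

#: Default reference temperature: 28 degC in Kelvin.
T0_DEFAULT: float = 301.15


def celsius_to_kelvin(t_c):
    """Convert Celsius to Kelvin (scalar or array)."""
    return np.asarray(t_c, dtype=float) + 273.15 if np.ndim(t_c) else float(t_c) + 273.15


def kelvin_to_celsius(t_k):
    """Convert Kelvin to Celsius (scalar or array)."""
    return np.asarray(t_k, dtype=float) - 273.15 if np.ndim(t_k) else float(t_k) - 273.15


@dataclass(frozen=True)
class BDPParams:
    """Rate parameters of the birth--death process at one temperature.

    Parameters
    ----------
    theta1 : float
        Per-capita birth rate in the absence of density dependence (day^-1).
    theta2 : float
        Strength of density dependence on births (dimensionless).
    theta3 : float
        Per-capita death rate (day^-1).
    N : int
        Population size at which the birth probability vanishes (individuals).
    """

    theta1: float
    theta2: float
    theta3: float
    N: int

    def __post_init__(self) -> None:
        if not self.theta1 > 0:
            raise ValueError(f"theta1 must be > 0, got {self.theta1}")
        if not self.theta2 > 0:
            raise ValueError(f"theta2 must be > 0, got {self.theta2}")
        if self.theta3 < 0:
            raise ValueError(f"theta3 must be >= 0, got {self.theta3}")
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")

    @property
    def r(self) -> float:
        """Maximum population growth rate theta1 - theta3 (day^-1)."""
        return self.theta1 - self.theta3

    @property
    def K(self) -> float:
        """Carrying capacity N*(theta1-theta3)/(theta1*theta2); <= 0 if not growing."""
        return self.N * (self.theta1 - self.theta3) / (self.theta1 * self.theta2)

    def require_growing(self) -> "BDPParams":
        """Validate r > 0 (needed for growth-scenario simulation); return self."""
        if self.r <= 0:
            raise ValueError(
                f"non-growing parameter set: r = theta1 - theta3 = {self.r} <= 0"
            )
        return self


@dataclass(frozen=True)
class LogisticParams:
    """Logistic-equation parameters: growth rate r (day^-1), carrying capacity K, n0."""

    r: float
    K: float
    n0: float = 0.0

    def __post_init__(self) -> None:
        if self.n0 < 0:
            raise ValueError(f"n0 must be >= 0, got {self.n0}")

    @property
    def growing(self) -> bool:
        return self.r > 0 and self.K > 0


@dataclass(frozen=True)
class ArrheniusModel:
    """Baseline birth--death rates at T0 plus per-parameter activation energies.

    ``e_a`` may be a single shared activation energy (applied to all three
    rate parameters) or a triple ``(E_1, E_2, E_3)``.  The biologically
    interpretable pair (E_A,r, E_A,K) maps onto the triple as
    ``(E_A,r, E_A,K, E_A,r)``: with theta1 and theta3 sharing E_A,r the growth
    rate scales with E_A,r, and because K is proportional to 1/theta2 the
    carrying capacity scales as ``exp(+(E_A,K/kB)(1/T - 1/T0))``.
    """

    theta01: float
    theta02: float
    theta03: float
    e_a: float | tuple[float, float, float]
    T0: float = T0_DEFAULT
    N: int = 15000
    kB: float = field(default=KB)

    def __post_init__(self) -> None:
        if not self.T0 > 0:
            raise ValueError(f"T0 must be > 0 K, got {self.T0}")
        eas = self.e_a_triple
        if not all(math.isfinite(e) for e in eas):
            raise ValueError(f"activation energies must be finite, got {eas}")
        # validate baselines via BDPParams
        BDPParams(self.theta01, self.theta02, self.theta03, self.N)

    @property
    def e_a_triple(self) -> tuple[float, float, float]:
        if isinstance(self.e_a, (tuple, list)):
            if len(self.e_a) != 3:
                raise ValueError("e_a must be a scalar or a triple")
            return tuple(float(e) for e in self.e_a)
        return (float(self.e_a), float(self.e_a), float(self.e_a))

    @property
    def shared_e_a(self) -> bool:
        e1, e2, e3 = self.e_a_triple
        return e1 == e2 == e3

    @property
    def e_a_r(self) -> float:
        """Activation energy of the growth rate (requires E_1 == E_3)."""
        e1, _, e3 = self.e_a_triple
        if e1 != e3:
            raise ValueError("E_A,r undefined: theta1 and theta3 have different E_A")
        return e1

    @property
    def e_a_k(self) -> float:
        """Activation energy of the carrying capacity (K ~ exp(+E_A,K*(1/T-1/T0)/kB))."""
        _, e2, _ = self.e_a_triple
        self.e_a_r  # noqa: B018 -- raises if r-scaling is not Arrhenius
        return e2

    @classmethod
    def from_r_k(
        cls,
        theta01: float,
        theta02: float,
        theta03: float,
        e_a_r: float,
        e_a_k: float,
        T0: float = T0_DEFAULT,
        N: int = 15000,
    ) -> "ArrheniusModel":
        """Build a model from the (E_A,r, E_A,K) parameterization of the case study."""
        return cls(theta01, theta02, theta03, (e_a_r, e_a_k, e_a_r), T0=T0, N=N)

    def baseline(self) -> BDPParams:
        return BDPParams(self.theta01, self.theta02, self.theta03, self.N)


def arrhenius_scale(
    theta0: float, e_a: float, T: float, T0: float = T0_DEFAULT, kB: float = KB
) -> float:
    """Scale a rate from the reference temperature T0 to temperature T (Kelvin).

    Returns ``theta0 * exp(-(e_a/kB) * (1/T - 1/T0))``; strictly increasing in
    T when ``e_a > 0``.
    """
    if not (T > 0 and T0 > 0):
        raise ValueError(f"temperatures must be positive Kelvin, got T={T}, T0={T0}")
    if not theta0 > 0:
        raise ValueError(f"theta0 must be > 0, got {theta0}")
    return theta0 * math.exp(-(e_a / kB) * (1.0 / T - 1.0 / T0))


def derive_logistic(params: BDPParams, n0: float = 0.0) -> LogisticParams:
    """Derive logistic r and K from birth--death rates.

    For ``theta1 <= theta3`` the population is non-growing; K is then <= 0 and
    flagged by ``LogisticParams.growing`` rather than raised, since inference
    may legitimately wander through that region.
    """
    r = params.theta1 - params.theta3
    K = params.N * r / (params.theta1 * params.theta2)
    return LogisticParams(r=r, K=K, n0=n0)


def logistic_mean(t, lp: LogisticParams):
    """Mean abundance of the logistic equation at time(s) ``t`` (days).

    Closed form ``K*n0*e^{rt} / (K + n0*(e^{rt} - 1))``.  For ``r == 0`` the
    process is at pure birth--death balance and the mean is constant ``n0``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if lp.r == 0.0:
        out = np.full_like(t, float(lp.n0))
        return out if out.ndim else float(out)
    if lp.n0 == 0.0:
        out = np.zeros_like(t)
        return out if out.ndim else float(out)
    ert = np.exp(lp.r * t)
    out = lp.K * lp.n0 * ert / (lp.K + lp.n0 * (ert - 1.0))
    return out if out.ndim else float(out)


def scale_model(model: ArrheniusModel, T: float) -> BDPParams:
    """Evaluate the Arrhenius model at temperature T (Kelvin) -> BDPParams."""
    e1, e2, e3 = model.e_a_triple
    return BDPParams(
        theta1=arrhenius_scale(model.theta01, e1, T, model.T0, model.kB),
        theta2=arrhenius_scale(model.theta02, e2, T, model.T0, model.kB),
        theta3=(
            arrhenius_scale(model.theta03, e3, T, model.T0, model.kB)
            if model.theta03 > 0
            else 0.0
        ),
        N=model.N,
    )
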