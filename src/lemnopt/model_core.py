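"""Canopy growth kinetics for free-floating macrophyte mats.

The growth rate of an areal dry-biomass density ``D`` under a surface photon
flux ``I_S`` is modelled as photoperiod-scaled photosynthesis minus constant
respiration.  Mutual shading inside the floating plant layer follows an
exponential (Beer-Lambert) attenuation of light with depth, and the local
photosynthetic response to light is of Monod type.  Averaging the Monod
factor over the layer thickness (taken proportional to ``D``) gives a closed
form for the mean limitation of photosynthesis, which makes the model a
one-dimensional autonomous ODE per light level.

The module also carries a published logistic-type comparator model so both
right-hand sides can be fitted and simulated through a common interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import ConfigurationError, DomainError, IntegrationError, NoFiniteLimitError

__all__ = [
    "GrowthParams",
    "VanDyckParams",
    "Trajectory",
    "BiomassSample",
    "REFERENCE_PARAMS",
    "REFERENCE_VANDYCK_PARAMS",
    "DEFAULT_PHOTOPERIOD",
    "SMALL_DEPTH_THRESHOLD",
    "mean_photosynthesis_limitation",
    "depth_resolved_limitation",
    "growth_rate",
    "vandyck_growth_rate",
    "simulate",
    "limit_density",
    "compensation_intensity",
    "dry_weight_content",
    "lai_estimate",
]

#: Illuminated fraction of the 24 h cycle used throughout (14 h light).
DEFAULT_PHOTOPERIOD = 14.0 / 24.0

#: Below this value of the dimensionless optical depth ``eps_hat * D`` the
#: closed-form mean limitation is evaluated by its analytic zero-depth limit
#: ``I_S / (k + I_S)`` to avoid 0/0 cancellation.
SMALL_DEPTH_THRESHOLD = 1e-8


@dataclass(frozen=True)
class GrowthParams:
    """Kinetic parameters of the canopy-shading growth model.

    Attributes
    ----------
    r_phot_i:
        Intrinsic photosynthesis rate at full light saturation, d^-1.
    r_resp:
        Respiration rate, d^-1.
    eps_hat:
        Light attenuation constant per areal density, m^2 gDW^-1.  This is
        the identifiable product of the per-thickness attenuation constant
        and the layer-thickness-per-density constant; the two factors are
        never represented separately.
    k:
        Half-saturation light intensity of the Monod response,
        umol m^-2 s^-1.
    E:
        Photoperiod as illuminated fraction of the cycle, dimensionless.
    """

    r_phot_i: float
    r_resp: float
    eps_hat: float
    k: float
    E: float = DEFAULT_PHOTOPERIOD

    def __post_init__(self) -> None:
        if not self.r_phot_i > 0:
            raise ConfigurationError(f"r_phot_i must be > 0, got {self.r_phot_i}")
        if self.r_resp < 0:
            raise ConfigurationError(f"r_resp must be >= 0, got {self.r_resp}")
        if not self.eps_hat > 0:
            raise ConfigurationError(f"eps_hat must be > 0, got {self.eps_hat}")
        if not self.k > 0:
            raise ConfigurationError(f"k must be > 0, got {self.k}")
        if not 0 < self.E <= 1:
            raise ConfigurationError(f"E must be in (0, 1], got {self.E}")


@dataclass(frozen=True)
class VanDyckParams:
    """Parameters of the logistic-capacity comparator model.

    ``h_D`` plays the role of a density capacity and therefore carries the
    unit gDW m^-2 (areal density), ``K_I`` is the Monod half-saturation
    light intensity.
    """

    r_phot_i: float
    r_resp: float
    h_D: float
    K_I: float
    E: float = DEFAULT_PHOTOPERIOD

    def __post_init__(self) -> None:
        for name in ("r_phot_i", "r_resp", "h_D", "K_I"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 < self.E <= 1:
            raise ConfigurationError(f"E must be in (0, 1], got {self.E}")


ModelParams = Union[GrowthParams, VanDyckParams]

#: Reference fitted parameter values for *Lemna minor* grown in a
#: recirculating indoor vertical farm under a 14 h photoperiod.  Used as
#: ground truth for synthetic data and as CLI defaults.
REFERENCE_PARAMS = GrowthParams(
    r_phot_i=0.6965, r_resp=0.0583, eps_hat=0.1209, k=17.2640, E=DEFAULT_PHOTOPERIOD
)

#: Reference fitted values of the comparator model on the same culture.
REFERENCE_VANDYCK_PARAMS = VanDyckParams(
    r_phot_i=0.4602, r_resp=0.0788, h_D=223.7906, K_I=50.4300, E=DEFAULT_PHOTOPERIOD
)


@dataclass(frozen=True)
class Trajectory:
    """A simulated density trajectory at constant surface light intensity."""

    times: np.ndarray
    densities: np.ndarray
    I_S: float
    params: ModelParams
    method: str = "RK45"
    step: float = 0.05

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        dens = np.asarray(self.densities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "densities", dens)
        if times.ndim != 1 or dens.shape != times.shape:
            raise ConfigurationError("times and densities must be 1-D arrays of equal length")
        if times[0] != 0 or np.any(np.diff(times) <= 0):
            raise ConfigurationError("times must be strictly increasing from 0")
        if np.any(dens < 0):
            raise ConfigurationError("densities must be non-negative")

    @property
    def final_density(self) -> float:
        return float(self.densities[-1])


@dataclass(frozen=True)
class BiomassSample:
    """Paired fresh/dry weight of a harvested biomass sample."""

    fresh_weight: float
    dry_weight: float
    area: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.dry_weight <= self.fresh_weight:
            raise DomainError(
                f"need 0 < dry_weight <= fresh_weight, got DW={self.dry_weight}, FW={self.fresh_weight}"
            )


def _check_nonnegative(name: str, value: np.ndarray | float) -> None:
    if np.any(np.asarray(value) < 0):
        raise DomainError(f"{name} must be non-negative")


def mean_photosynthesis_limitation(I_S, D, params: GrowthParams):
    """Mean Monod light-limitation factor of the whole plant layer.

    Closed form of the depth average of ``I(z) / (k + I(z))`` with
    ``I(z) = I_S * exp(-eps_hat * D * s)``, ``s`` in [0, 1]:

        fbar = [ln(k + I_S) - ln(k + I_S * exp(-eps_hat * D))] / (eps_hat * D)

    For ``eps_hat * D`` below :data:`SMALL_DEPTH_THRESHOLD` the analytic
    zero-depth limit ``I_S / (k + I_S)`` is returned instead.  Accepts
    scalars or arrays (broadcast), returns the matching shape.
    """
    I_S = np.asarray(I_S, dtype=float)
    D = np.asarray(D, dtype=float)
    _check_nonnegative("I_S", I_S)
    _check_nonnegative("D", D)
    x = params.eps_hat * D
    small = x < SMALL_DEPTH_THRESHOLD
    x_safe = np.where(small, 1.0, x)
    # log-difference written via log1p/expm1: identical analytically, but
    # immune to the catastrophic cancellation of ln(k+I) - ln(k+I e^-x)
    # for small optical depth x.
    with np.errstate(divide="ignore", invalid="ignore"):
        main = -np.log1p(I_S * np.expm1(-x_safe) / (params.k + I_S)) / x_safe
    limit = I_S / (params.k + I_S)
    out = np.where(small, limit, main)
    if out.ndim == 0:
        return float(out)
    return out


def depth_resolved_limitation(I_S, attenuation_exponent, params: GrowthParams):
    """Monod limitation factor at a given optical depth inside the layer.

    ``attenuation_exponent`` is the dimensionless product eps_hat * D * s
    for a relative depth s in [0, 1]; the local intensity is
    ``I_S * exp(-attenuation_exponent)``.
    """
    I_S = np.asarray(I_S, dtype=float)
    e = np.asarray(attenuation_exponent, dtype=float)
    _check_nonnegative("I_S", I_S)
    _check_nonnegative("attenuation exponent", e)
    I = I_S * np.exp(-e)
    out = I / (params.k + I)
    if out.ndim == 0:
        return float(out)
    return out


def growth_rate(D, I_S, params: GrowthParams):
    """Net growth rate dD/dt of the canopy-shading model, gDW m^-2 d^-1."""
    D = np.asarray(D, dtype=float)
    fbar = mean_photosynthesis_limitation(I_S, D, params)
    out = D * (params.E * params.r_phot_i * fbar - params.r_resp)
    if out.ndim == 0:
        return float(out)
    return out


def vandyck_growth_rate(D, I, params: VanDyckParams):
    """Net growth rate dD/dt of the logistic-capacity comparator model."""
    D = np.asarray(D, dtype=float)
    I = np.asarray(I, dtype=float)
    _check_nonnegative("D", D)
    _check_nonnegative("I", I)
    monod = I / (params.K_I + I)
    out = D * (params.r_phot_i * (1.0 - D / params.h_D) * params.E * monod - params.r_resp)
    if out.ndim == 0:
        return float(out)
    return out


def _make_rhs(params: ModelParams, I_S: float) -> Callable:
    if isinstance(params, GrowthParams):
        return lambda t, D: growth_rate(D, I_S, params)
    if isinstance(params, VanDyckParams):
        return lambda t, D: vandyck_growth_rate(D, I_S, params)
    raise TypeError(f"unsupported parameter type {type(params)!r}")


def simulate(
    D_0: float,
    I_S: float,
    params: ModelParams,
    t_end: float,
    step: float = 0.05,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the density ODE from ``D_0`` at constant ``I_S``.

    A Dormand-Prince (RK45) pair with embedded error control does the
    integration; the dense output is sampled on the regular reporting grid
    of the requested ``step`` (0.05 d by default), always including
    ``t_end`` itself.
    """
    _check_nonnegative("D_0", D_0)
    _check_nonnegative("I_S", I_S)
    if not t_end > 0:
        raise DomainError(f"t_end must be > 0, got {t_end}")
    if not step > 0:
        raise DomainError(f"step must be > 0, got {step}")
    rhs = _make_rhs(params, float(I_S))
    sol = solve_ivp(
        rhs,
        (0.0, float(t_end)),
        [float(D_0)],
        method="RK45",
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed (D_0={D_0}, I_S={I_S}, t_end={t_end}): {sol.message}"
        )
    times = np.arange(0.0, t_end, step)
    if times.size == 0 or not math.isclose(times[-1], t_end):
        times = np.append(times, t_end)
    densities = sol.sol(times)[0]
    # dense-output interpolation can undershoot 0 by round-off near D = 0
    densities = np.where((densities < 0) & (densities > -atol), 0.0, densities)
    if np.any(~np.isfinite(densities)):
        raise IntegrationError("non-finite state in integrated trajectory")
    densities = densities.copy()
    densities[0] = float(D_0)
    return Trajectory(times=times, densities=densities, I_S=float(I_S), params=params, step=step)


def simulate_terminal_batch(
    D_0: np.ndarray,
    I_S: np.ndarray,
    params: ModelParams,
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Terminal densities of many independent trajectories in one solve.

    Because the trajectories do not interact, they are stacked into a single
    vector-valued ODE and integrated together, which is far cheaper than one
    ``solve_ivp`` call each.  Used by the fitting and optimization layers.
    """
    D_0 = np.asarray(D_0, dtype=float)
    I_S = np.asarray(I_S, dtype=float)
    if D_0.shape != I_S.shape:
        raise ConfigurationError("D_0 and I_S must have the same shape")
    if t_end == 0:
        return D_0.copy()
    if isinstance(params, GrowthParams):
        rhs = lambda t, D: growth_rate(D, I_S, params)  # noqa: E731
    elif isinstance(params, VanDyckParams):
        rhs = lambda t, D: vandyck_growth_rate(np.maximum(D, 0.0), I_S, params)  # noqa: E731
    else:
        raise TypeError(f"unsupported parameter type {type(params)!r}")
    sol = solve_ivp(rhs, (0.0, float(t_end)), D_0, method="RK45", rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"batch ODE integration failed: {sol.message}")
    return sol.y[:, -1]


def compensation_intensity(params: GrowthParams) -> float:
    """Light intensity at which vanishing-density growth exactly balances.

    Solves ``E * r_phot_i * I / (k + I) = r_resp`` for I; infinite when
    respiration exceeds the saturated photosynthesis rate.
    """
    net = params.E * params.r_phot_i - params.r_resp
    if net <= 0:
        return math.inf
    return params.r_resp * params.k / net


def limit_density(I_S: float, params: GrowthParams, residual_tol: float = 1e-9) -> float:
    """Carrying capacity: the density where net per-capita growth is zero.

    Returns 0 when ``I_S`` is at or below the compensation intensity.  Found
    by bracketed root finding on the per-capita rate; the long-horizon
    simulation plateau agrees with this root (used as a cross-check in the
    test-suite, not here).
    """
    _check_nonnegative("I_S", I_S)
    if params.r_resp == 0:
        raise NoFiniteLimitError("r_resp = 0: density grows without bound, no finite limit")
    I_S = float(I_S)

    def percapita(D: float) -> float:
        return (
            params.E * params.r_phot_i * mean_photosynthesis_limitation(I_S, D, params)
            - params.r_resp
        )

    if percapita(0.0) <= 0:
        return 0.0
    lo, hi = 1e-12, 1.0
    while percapita(hi) > 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for valid params
            raise NoFiniteLimitError("per-capita rate does not change sign")
    root = brentq(percapita, lo, hi, xtol=1e-13, rtol=4 * np.finfo(float).eps)
    if abs(percapita(root)) > residual_tol:
        raise IntegrationError(f"limit-density root residual {percapita(root):.2e} > {residual_tol}")
    return float(root)


def dry_weight_content(sample: BiomassSample) -> float:
    """Dry-weight fraction DW/FW of a biomass sample, in (0, 1]."""
    return sample.dry_weight / sample.fresh_weight


def lai_estimate(D: float, lma: float = 11.5) -> float:
    """Leaf area index estimated from areal density and leaf mass per area."""
    _check_nonnegative("D", D)
    if not lma > 0:
        raise DomainError(f"LMA must be > 0, got {lma}")
    return float(D) / float(lma)
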