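"""Semi-continuous harvest-process optimization layer.

A fraction of the standing crop is removed every ``delta_t_H`` days, leaving
a residual density that regrows until the next harvest.  For a given surface
light intensity the layer finds the residual density maximizing the average
daily yield, the yield itself, the light-use efficiency (harvested dry mass
per delivered photon dose) and the intensity maximizing that efficiency.
``delta_t_H = 0`` denotes continuous harvesting, whose cycle yield is the
instantaneous net growth rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import DegenerateOptimumError, DomainError
from .model_core import (
    GrowthParams,
    growth_rate,
    limit_density,
    simulate,
    simulate_terminal_batch,
)

__all__ = [
    "HarvestPlan",
    "OptimizationResult",
    "LUE_CONVENTIONS",
    "cycle_average_yield",
    "optimal_residual_density",
    "max_daily_yield",
    "light_use_efficiency",
    "photon_dose",
    "lue_optimal_intensity",
    "sweep",
    "sweep_to_dataframe",
]

#: Conversions from a surface intensity in umol m^-2 s^-1 to the daily
#: delivered photon dose used in the LUE denominator.
#: ``daily_mmol``: photons delivered only during the illuminated fraction E,
#: expressed in mmol m^-2 d^-1.  ``raw``: the intensity itself (no unit
#: conversion); both share the same argmax over intensity.
LUE_CONVENTIONS = ("daily_mmol", "raw")

LueConvention = Literal["daily_mmol", "raw"]

_SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class HarvestPlan:
    """Harvest interval in days; 0 means continuous harvesting."""

    delta_t_H: float

    def __post_init__(self) -> None:
        if self.delta_t_H < 0:
            raise DomainError(f"delta_t_H must be >= 0, got {self.delta_t_H}")


@dataclass(frozen=True)
class OptimizationResult:
    """One optimized operating point of the harvest process."""

    I_S: float
    delta_t_H: float
    d_opt: float
    m_dot_max: float
    lue: float
    convention: str
    error: str | None = None


def cycle_average_yield(
    D_start: float, plan: HarvestPlan, I_S: float, params: GrowthParams
) -> float:
    """Average daily harvestable mass over one regrowth cycle.

    For a positive interval: (D(delta_t_H; D_start) - D_start) / delta_t_H.
    For continuous harvesting the instantaneous net growth rate.
    """
    if not D_start > 0:
        raise DomainError(f"D_start must be > 0, got {D_start}")
    dt = plan.delta_t_H
    if dt == 0:
        return growth_rate(D_start, I_S, params)
    traj = simulate(D_start, I_S, params, dt)
    return (traj.final_density - D_start) / dt


def _cycle_yield_batch(
    d_starts: np.ndarray, dt: float, I_S: float, params: GrowthParams
) -> np.ndarray:
    if dt == 0:
        return growth_rate(d_starts, I_S, params)
    i_s = np.full_like(d_starts, float(I_S))
    finals = simulate_terminal_batch(d_starts, i_s, params, dt)
    return (finals - d_starts) / dt


def _optimize_cell(
    plan: HarvestPlan,
    I_S: float,
    params: GrowthParams,
    d_l: float | None = None,
    coarse: int = 33,
    xatol: float = 1e-6,
) -> tuple[float, float]:
    """(d_opt, m_dot_max) for one (interval, intensity) cell.

    A coarse grid over (0, D_L) locates the mode (and checks the profile is
    single-peaked); a bounded scalar search refines it to ``xatol``.
    """
    if d_l is None:
        d_l = limit_density(I_S, params)
    if d_l <= 0:
        return 0.0, 0.0
    dt = plan.delta_t_H
    eps = 1e-9 * d_l
    grid = np.linspace(eps, d_l - eps, coarse)
    vals = _cycle_yield_batch(grid, dt, I_S, params)
    i_best = int(np.argmax(vals))
    # sanity: a unimodal profile rises then falls around the grid argmax
    rising = np.diff(vals[: i_best + 1]) >= -1e-12 * max(1.0, abs(vals[i_best]))
    falling = np.diff(vals[i_best:]) <= 1e-12 * max(1.0, abs(vals[i_best]))
    if not (rising.all() and falling.all()):  # pragma: no cover - guard only
        # fall back to a denser grid before refining
        grid = np.linspace(eps, d_l - eps, 20 * coarse)
        vals = _cycle_yield_batch(grid, dt, I_S, params)
        i_best = int(np.argmax(vals))
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda d: -cycle_average_yield(d, plan, I_S, params),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": xatol},
    )
    d_opt = float(res.x)
    m_dot = -float(res.fun)
    if m_dot < vals[i_best]:  # refinement must never lose to the grid
        d_opt, m_dot = float(grid[i_best]), float(vals[i_best])
    return d_opt, m_dot


def optimal_residual_density(
    plan: HarvestPlan, I_S: float, params: GrowthParams
) -> float:
    """Residual density maximizing the cycle-average yield, gDW m^-2."""
    return _optimize_cell(plan, I_S, params)[0]


def max_daily_yield(plan: HarvestPlan, I_S: float, params: GrowthParams) -> float:
    """Cycle-average yield at the optimal residual density, gDW m^-2 d^-1."""
    return _optimize_cell(plan, I_S, params)[1]


def photon_dose(I_S: float, E: float, convention: LueConvention = "daily_mmol") -> float:
    """LUE denominator for a surface intensity, per the chosen convention."""
    if convention == "daily_mmol":
        return I_S * E * _SECONDS_PER_DAY / 1000.0
    if convention == "raw":
        return float(I_S)
    raise DomainError(f"unknown LUE convention {convention!r}")


def light_use_efficiency(
    plan: HarvestPlan,
    I_S: float,
    params: GrowthParams,
    convention: LueConvention = "daily_mmol",
) -> float:
    """Harvested dry mass per delivered photon dose at the optimal density."""
    if not I_S > 0:
        raise DomainError("LUE is undefined at I_S = 0")
    m_dot = max_daily_yield(plan, I_S, params)
    return m_dot / photon_dose(I_S, params.E, convention)


def lue_optimal_intensity(
    plan: HarvestPlan,
    params: GrowthParams,
    convention: LueConvention = "daily_mmol",
    i_max: float = 500.0,
    grid_size: int = 60,
    xatol: float = 0.01,
) -> float:
    """Intensity in (0, i_max] maximizing the light-use efficiency.

    A geometric coarse grid locates the peak, a bounded scalar search
    refines it.  Raises :class:`DegenerateOptimumError` when no intensity
    yields positive efficiency (net growth impossible anywhere).
    """
    grid = np.geomspace(0.1, i_max, grid_size)
    lues = np.array([light_use_efficiency(plan, i, params, convention) for i in grid])
    if not np.any(lues > 0):
        raise DegenerateOptimumError("light-use efficiency is non-positive everywhere")
    i_best = int(np.argmax(lues))
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda i: -light_use_efficiency(plan, i, params, convention),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": xatol},
    )
    if -res.fun >= lues[i_best]:
        return float(res.x)
    return float(grid[i_best])


def sweep(
    params: GrowthParams,
    i_s_grid: Sequence[float],
    delta_t_h_set: Sequence[float],
    convention: LueConvention = "daily_mmol",
) -> list[OptimizationResult]:
    """Optimize every (I_S, delta_t_H) cell; failures are recorded per cell."""
    i_s_grid = list(i_s_grid)
    delta_t_h_set = list(delta_t_h_set)
    if not i_s_grid or not delta_t_h_set:
        raise DomainError("sweep grids must be non-empty")
    results: list[OptimizationResult] = []
    for i_s in i_s_grid:
        try:
            d_l = limit_density(i_s, params)
        except Exception as exc:  # record and continue with the next column
            for dt in delta_t_h_set:
                results.append(
                    OptimizationResult(i_s, dt, math.nan, math.nan, math.nan, convention, str(exc))
                )
            continue
        for dt in delta_t_h_set:
            try:
                plan = HarvestPlan(dt)
                d_opt, m_dot = _optimize_cell(plan, i_s, params, d_l=d_l)
                lue = m_dot / photon_dose(i_s, params.E, convention) if i_s > 0 else math.nan
                results.append(OptimizationResult(i_s, dt, d_opt, m_dot, lue, convention))
            except Exception as exc:
                results.append(
                    OptimizationResult(i_s, dt, math.nan, math.nan, math.nan, convention, str(exc))
                )
    return results


SWEEP_COLUMNS = [
    "i_s_umol_m2_s",
    "delta_t_h_d",
    "d_opt_gdw_m2",
    "m_dot_max_gdw_m2_d",
    "lue_gdw_mmol",
]


def sweep_to_dataframe(results: Iterable[OptimizationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.I_S, r.delta_t_H, r.d_opt, r.m_dot_max, r.lue) for r in results],
        columns=SWEEP_COLUMNS,
    )
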