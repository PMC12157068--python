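"""Synthetic dataset generators mirroring the experimental designs.

Every generator is a pure function of its inputs and seed, producing the
same CSV dialects the fitting and light-field layers consume.  Ground truth
defaults to the reference fitted parameter set, so end-to-end recovery tests
can compare estimates against a known truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError
from .fitting import LongTermSeries, TrialRecord
from .light_field import PARMeasurement
from .model_core import GrowthParams, REFERENCE_PARAMS, simulate_terminal_batch

__all__ = [
    "TrialDesign",
    "NoiseSpec",
    "Lamp",
    "LightSurvey",
    "generate_trials",
    "generate_longterm",
    "generate_light_survey",
    "default_lamp_row",
    "manifest",
]

#: Long-term validation light levels, umol m^-2 s^-1.
LONGTERM_INTENSITIES = (58.4, 109.2, 136.0, 168.1)


@dataclass(frozen=True)
class TrialDesign:
    """Full-factorial growth-trial design (densities x intensities x reps)."""

    initial_densities: tuple[float, ...] = (10.0, 42.0, 74.0, 106.0, 138.0, 170.0)
    light_intensities: tuple[float, ...] = (42.7, 88.2, 123.9, 166.2)
    replicates: int = 5
    duration: float = 7.0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.initial_densities):
            raise ConfigurationError("initial densities must be positive")
        if any(i <= 0 for i in self.light_intensities):
            raise ConfigurationError("light intensities must be positive")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if not self.duration > 0:
            raise ConfigurationError("duration must be > 0")

    @property
    def n_trials(self) -> int:
        return len(self.initial_densities) * len(self.light_intensities) * self.replicates


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise coefficients of variation (placeholders, not
    estimated from any published dataset) and the RNG seed.

    Noise is multiplicative and mean-one (lognormal), placed on the observed
    final density; small jitters on the initial density and per-ring light
    intensity mimic the post-hoc dry-weight correction and ring-to-ring
    light variation.
    """

    d7_cv: float = 0.05
    i_s_cv: float = 0.05
    d0_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.d7_cv, self.i_s_cv, self.d0_cv) < 0:
            raise ConfigurationError("noise CVs must be >= 0")


def _meanone_lognormal(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative factors with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_trials(
    params: GrowthParams = REFERENCE_PARAMS,
    design: TrialDesign = TrialDesign(),
    noise: NoiseSpec = NoiseSpec(),
) -> list[TrialRecord]:
    """Simulate the full factorial trial design with observation noise."""
    rng = np.random.default_rng(noise.seed)
    cells = [
        (d0, i_s)
        for d0 in design.initial_densities
        for i_s in design.light_intensities
        for _ in range(design.replicates)
    ]
    n = len(cells)
    d0 = np.array([c[0] for c in cells]) * _meanone_lognormal(rng, noise.d0_cv, n)
    i_s = np.array([c[1] for c in cells]) * _meanone_lognormal(rng, noise.i_s_cv, n)
    d7_true = simulate_terminal_batch(d0, i_s, params, design.duration)
    d7 = d7_true * _meanone_lognormal(rng, noise.d7_cv, n)
    trials = []
    rep_counter: dict[tuple[float, float], int] = {}
    for j, (d0_nom, i_nom) in enumerate(cells):
        rep = rep_counter.get((d0_nom, i_nom), 0) + 1
        rep_counter[(d0_nom, i_nom)] = rep
        trials.append(
            TrialRecord(
                trial_id=f"d{d0_nom:05.1f}-i{i_nom:05.1f}-r{rep}",
                I_S=float(i_s[j]),
                D_0=float(d0[j]),
                D_7=float(d7[j]),
                duration=design.duration,
            )
        )
    return trials


def generate_longterm(
    params: GrowthParams = REFERENCE_PARAMS,
    intensities: Sequence[float] = LONGTERM_INTENSITIES,
    d_0: float = 17.0,
    horizon: float = 56.0,
    cadence: float = 14.0,
    noise_cv: float = 0.03,
    seed: int = 0,
) -> list[LongTermSeries]:
    """Biweekly long-term observation series at several light levels."""
    if horizon <= 0 or cadence <= 0 or abs(horizon / cadence - round(horizon / cadence)) > 1e-9:
        raise DomainError("horizon must be a positive multiple of the cadence")
    if noise_cv < 0:
        raise DomainError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, horizon + cadence / 2, cadence)
    out = []
    for i_s in intensities:
        dens = np.empty_like(times)
        dens[0] = d_0
        if times.size > 1:
            dens[1:] = _densities_on_grid(d_0, float(i_s), params, times[1:])
        obs = dens * _meanone_lognormal(rng, noise_cv, times.size)
        out.append(
            LongTermSeries(
                series_id=f"lt-i{i_s:05.1f}", I_S=float(i_s), times=times, densities=obs
            )
        )
    return out


def _densities_on_grid(d_0, i_s, params, times) -> np.ndarray:
    from scipy.integrate import solve_ivp

    from .model_core import _make_rhs

    sol = solve_ivp(
        _make_rhs(params, i_s),
        (0.0, float(times[-1])),
        [float(d_0)],
        method="RK45",
        rtol=1e-8,
        atol=1e-10,
        t_eval=times,
    )
    return sol.y[0]


@dataclass(frozen=True)
class Lamp:
    """A light source modelled as an anisotropic Gaussian footprint."""

    x: float
    y: float
    peak: float  # umol m^-2 s^-1 directly under the lamp
    sigma_x: float
    sigma_y: float

    def intensity(self, x, y) -> np.ndarray:
        return self.peak * np.exp(
            -((np.asarray(x) - self.x) ** 2) / (2 * self.sigma_x**2)
            - ((np.asarray(y) - self.y) ** 2) / (2 * self.sigma_y**2)
        )


def default_lamp_row(
    n_lamps: int = 5,
    extent_x: float = 1200.0,
    y: float = 360.0,
    peak: float = 160.0,
    sigma_x: float = 260.0,
    sigma_y: float = 320.0,
) -> list[Lamp]:
    """A row of lamps across the basin, like a rail of LED modules."""
    xs = np.linspace(extent_x / (n_lamps + 1), extent_x * n_lamps / (n_lamps + 1), n_lamps)
    return [Lamp(float(x), y, peak, sigma_x, sigma_y) for x in xs]


@dataclass(frozen=True)
class LightSurvey:
    """Sampled survey plus the ground-truth field it was drawn from."""

    measurements: list[PARMeasurement]
    truth: Callable[[np.ndarray, np.ndarray], np.ndarray]


def generate_light_survey(
    lamps: Sequence[Lamp] | None = None,
    n_points: int = 65,
    noise_sd: float = 1.0,
    seed: int = 0,
    background: float = 2.0,
    extent: tuple[float, float] = (1200.0, 720.0),
    grid_shape: tuple[int, int] | None = None,
) -> LightSurvey:
    """Sample a smooth lamp-sum field on a jittered grid with additive noise.

    The true field function is retained on the result so interpolation
    output can be scored against it.
    """
    if n_points < 3:
        raise DomainError("need at least 3 survey points")
    if lamps is None:
        lamps = default_lamp_row(extent_x=extent[0], y=extent[1] / 2)
    rng = np.random.default_rng(seed)

    def truth(x, y):
        total = np.full(np.broadcast(np.asarray(x), np.asarray(y)).shape, float(background))
        for lamp in lamps:
            total = total + lamp.intensity(x, y)
        return total

    if grid_shape is None:
        nx = int(np.ceil(np.sqrt(n_points * extent[0] / extent[1])))
        ny = int(np.ceil(n_points / nx))
    else:
        nx, ny = grid_shape
    gx, gy = np.meshgrid(
        np.linspace(0.05 * extent[0], 0.95 * extent[0], nx),
        np.linspace(0.05 * extent[1], 0.95 * extent[1], ny),
    )
    pts = np.column_stack([gx.ravel(), gy.ravel()])[:n_points]
    jitter = rng.uniform(-0.02, 0.02, size=pts.shape) * np.array(extent)
    pts = pts + jitter
    vals = truth(pts[:, 0], pts[:, 1])
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    vals = np.maximum(vals, 0.0)
    measurements = [PARMeasurement(float(x), float(y), float(v)) for (x, y), v in zip(pts, vals)]
    return LightSurvey(measurements=measurements, truth=truth)


def manifest(
    design: TrialDesign | None = None,
    noise: NoiseSpec | None = None,
    params: GrowthParams | None = None,
    extra: dict | None = None,
) -> dict:
    """Machine-readable record of what a synthetic dataset contains."""
    out = {
        "generator": "lemnopt.synthetic",
        "note": "noise CVs are placeholders, not estimates of any published replicate variability",
    }
    if design is not None:
        out["design"] = asdict(design)
    if noise is not None:
        out["noise"] = asdict(noise)
    if params is not None:
        out["truth_params"] = asdict(params)
    if extra:
        out.update(extra)
    return out
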