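"""Spatial interpolation of light-intensity surveys over a production basin.

A point survey of photosynthetic photon flux density (PPFD) is turned into a
continuous field by ordinary kriging with an anisotropic spherical variogram,
then averaged over circular ring subareas to give the per-ring mean surface
intensity used by the growth trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import least_squares

from .errors import ConfigurationError, DomainError, SingularSystemError

__all__ = [
    "PARMeasurement",
    "VariogramModel",
    "EmpiricalVariogram",
    "GridSpec",
    "KrigedField",
    "RingSpec",
    "empirical_variogram",
    "fit_spherical_variogram",
    "krige",
    "ring_average",
    "read_measurements_csv",
    "write_measurements_csv",
]


@dataclass(frozen=True)
class PARMeasurement:
    """A single PPFD reading at basin-plane coordinates (mm)."""

    x: float
    y: float
    intensity: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise DomainError("coordinates must be finite")
        if self.intensity < 0:
            raise DomainError(f"intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class VariogramModel:
    """Anisotropic spherical semivariance model.

    The anisotropy is a rotation by ``angle_deg`` (counter-clockwise from
    the x-axis to the major axis) plus scaling of the minor-axis component
    by ``major_range / minor_range``; the effective lag is evaluated against
    ``major_range``.
    """

    nugget: float
    partial_sill: float
    major_range: float
    minor_range: float
    angle_deg: float = 0.0
    family: str = "spherical"

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.partial_sill < 0:
            raise ConfigurationError("nugget and partial sill must be >= 0")
        if not 0 < self.minor_range <= self.major_range:
            raise ConfigurationError("need 0 < minor_range <= major_range")
        if self.family != "spherical":
            raise ConfigurationError(f"unsupported variogram family {self.family!r}")

    def effective_lag(self, dx, dy) -> np.ndarray:
        """Anisotropy-transformed lag length for lag vectors (dx, dy)."""
        phi = math.radians(self.angle_deg)
        u = dx * math.cos(phi) + dy * math.sin(phi)  # along major axis
        v = -dx * math.sin(phi) + dy * math.cos(phi)  # along minor axis
        return np.sqrt(u**2 + (v * self.major_range / self.minor_range) ** 2)

    def semivariance_at_lag(self, h) -> np.ndarray:
        """Spherical semivariance of an (already transformed) scalar lag."""
        h = np.asarray(h, dtype=float)
        a = self.major_range
        ratio = np.clip(h / a, 0.0, 1.0)
        gamma = self.nugget + self.partial_sill * (1.5 * ratio - 0.5 * ratio**3)
        return np.where(h == 0, self.nugget, gamma)

    def semivariance(self, dx, dy) -> np.ndarray:
        return self.semivariance_at_lag(self.effective_lag(dx, dy))


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Directionally binned semivariances with pair counts."""

    lags: np.ndarray  # (n_sectors, n_bins) bin-centre lags
    semivariances: np.ndarray  # same shape; NaN where a bin is empty
    counts: np.ndarray  # pair counts, same shape
    sector_angles_deg: np.ndarray  # (n_sectors,) sector-centre directions

    @property
    def n_nonempty(self) -> int:
        return int(np.sum(self.counts > 0))


@dataclass(frozen=True)
class GridSpec:
    """Regular prediction grid over a bounding box (node-centred)."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    nx: int = 100
    ny: int = 100

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ConfigurationError("bounding box must have positive extent")
        if self.nx < 2 or self.ny < 2:
            raise ConfigurationError("grid must be at least 2 x 2")

    @classmethod
    def from_measurements(cls, measurements: Sequence[PARMeasurement], nx: int = 100, ny: int = 100):
        xs = [m.x for m in measurements]
        ys = [m.y for m in measurements]
        return cls(min(xs), max(xs), min(ys), max(ys), nx, ny)

    def nodes(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.linspace(self.x_min, self.x_max, self.nx)
        y = np.linspace(self.y_min, self.y_max, self.ny)
        return np.meshgrid(x, y, indexing="xy")


@dataclass(frozen=True)
class KrigedField:
    """Interpolated intensity grid with its geometry."""

    grid: GridSpec
    values: np.ndarray  # (ny, nx)
    variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (self.grid.ny, self.grid.nx):
            raise ConfigurationError("values shape must match the grid spec")
        if not np.all(np.isfinite(vals)):
            raise ConfigurationError("field predictions must be finite")


@dataclass(frozen=True)
class RingSpec:
    """A circular ring subarea (centre in mm, diameter in mm)."""

    center_x: float
    center_y: float
    diameter: float = 237.6

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ConfigurationError(f"diameter must be > 0, got {self.diameter}")


def empirical_variogram(
    measurements: Sequence[PARMeasurement],
    n_bins: int = 12,
    max_lag: float | None = None,
    n_sectors: int = 1,
) -> EmpiricalVariogram:
    """Binned semivariances 0.5 * mean((z_i - z_j)^2) per lag/direction class.

    With ``n_sectors = 1`` the variogram is omnidirectional; otherwise pair
    directions (mod 180 deg) are classified into equal angular sectors.
    Empty bins are flagged with NaN semivariance and zero count.
    """
    if len(measurements) < 2:
        raise DomainError("need at least 2 measurements")
    if n_bins < 1 or n_sectors < 1:
        raise DomainError("n_bins and n_sectors must be >= 1")
    xy = np.array([(m.x, m.y) for m in measurements])
    z = np.array([m.intensity for m in measurements])
    iu, ju = np.triu_indices(len(z), k=1)
    dx = xy[ju, 0] - xy[iu, 0]
    dy = xy[ju, 1] - xy[iu, 1]
    h = np.hypot(dx, dy)
    sv = 0.5 * (z[iu] - z[ju]) ** 2
    if max_lag is None:
        max_lag = 0.5 * float(h.max())
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    angles = np.mod(np.degrees(np.arctan2(dy, dx)), 180.0)
    sector_width = 180.0 / n_sectors
    sector_idx = np.minimum((angles // sector_width).astype(int), n_sectors - 1)
    sector_angles = (np.arange(n_sectors) + 0.5) * sector_width

    lags = np.tile(centres, (n_sectors, 1))
    gammas = np.full((n_sectors, n_bins), np.nan)
    counts = np.zeros((n_sectors, n_bins), dtype=int)
    keep = h <= max_lag
    bin_idx = np.minimum(np.searchsorted(edges, h[keep], side="right") - 1, n_bins - 1)
    bin_idx = np.maximum(bin_idx, 0)
    for s, b, v in zip(sector_idx[keep], bin_idx, sv[keep]):
        counts[s, b] += 1
        if np.isnan(gammas[s, b]):
            gammas[s, b] = 0.0
        gammas[s, b] += v
    with np.errstate(invalid="ignore"):
        gammas = np.where(counts > 0, gammas / np.maximum(counts, 1), np.nan)
    return EmpiricalVariogram(lags, gammas, counts, sector_angles)


def fit_spherical_variogram(
    empirical: EmpiricalVariogram, anisotropy: bool = True
) -> VariogramModel:
    """Weighted least-squares spherical fit to a binned variogram.

    Bin weights are the pair counts.  With ``anisotropy`` the rotation angle
    and range ratio are free; the fit is repeated from a few angle starts
    and the best kept.  A zero fitted sill raises a degenerate-fit error.
    """
    mask = empirical.counts > 0
    if np.sum(mask) < 3:
        raise DomainError("need at least 3 non-empty bins to fit a variogram")
    lags = empirical.lags[mask]
    gam = empirical.semivariances[mask]
    w = np.sqrt(empirical.counts[mask].astype(float))
    theta = np.deg2rad(np.broadcast_to(empirical.sector_angles_deg[:, None], empirical.lags.shape))[
        mask
    ]
    dx = lags * np.cos(theta)
    dy = lags * np.sin(theta)
    sill0 = max(float(np.nanmax(gam)), 1e-12)
    a0 = max(float(lags.max()), 1e-9)
    n_sectors = empirical.sector_angles_deg.size
    free_aniso = anisotropy and n_sectors > 1

    def model_of(p: np.ndarray) -> VariogramModel:
        nugget, psill, a_major, ratio, angle = p
        return VariogramModel(
            nugget=max(nugget, 0.0),
            partial_sill=max(psill, 0.0),
            major_range=max(a_major, 1e-9),
            minor_range=max(a_major, 1e-9) * min(max(ratio, 1e-3), 1.0),
            angle_deg=float(angle) % 180.0,
        )

    def resid(p: np.ndarray) -> np.ndarray:
        return w * (model_of(p).semivariance(dx, dy) - gam)

    starts = [0.0] if not free_aniso else [0.0, 45.0, 90.0, 135.0]
    best = None
    for ang0 in starts:
        p0 = np.array([0.0, sill0, 0.7 * a0, 1.0 if not free_aniso else 0.7, ang0])
        lb = np.array([0.0, 1e-12, 1e-6, 1.0 - 1e-12 if not free_aniso else 1e-3, ang0 - 90.0])
        ub = np.array([sill0 * 2, sill0 * 10, a0 * 10, 1.0, ang0 + 90.0])
        p0 = np.clip(p0, lb, ub)
        try:
            res = least_squares(resid, p0, bounds=(lb, ub), method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:  # pragma: no cover
        raise DomainError("variogram fit failed from all starts")
    model = model_of(best.x)
    if model.partial_sill <= 1e-10 * sill0 and model.nugget <= 1e-10 * sill0:
        raise DomainError("degenerate variogram fit: zero sill")
    return model


def _check_duplicates(xy: np.ndarray) -> None:
    _, inverse, counts = np.unique(
        np.round(xy, 9), axis=0, return_inverse=True, return_counts=True
    )
    if np.any(counts > 1):
        dup = xy[np.flatnonzero(counts[inverse] > 1)]
        raise SingularSystemError(
            f"duplicate measurement coordinates make the kriging system singular: {dup[:4].tolist()}"
        )


def krige(
    measurements: Sequence[PARMeasurement],
    model: VariogramModel,
    grid: GridSpec | None = None,
    compute_variance: bool = False,
) -> KrigedField:
    """Ordinary kriging prediction of the field at every grid node.

    Weights are constrained to sum to one through a Lagrange multiplier, so
    the predictor is unbiased; with a zero nugget it is exact at the data
    locations.  The (n+1) x (n+1) kriging matrix is factorized once and
    reused for all nodes.
    """
    if len(measurements) < 2:
        raise DomainError("need at least 2 measurements to krige")
    xy = np.array([(m.x, m.y) for m in measurements])
    z = np.array([m.intensity for m in measurements])
    _check_duplicates(xy)
    if grid is None:
        grid = GridSpec.from_measurements(measurements)
    n = len(z)
    dx = xy[:, 0][:, None] - xy[:, 0][None, :]
    dy = xy[:, 1][:, None] - xy[:, 1][None, :]
    a_mat = np.empty((n + 1, n + 1))
    a_mat[:n, :n] = model.semivariance(dx, dy)
    np.fill_diagonal(a_mat[:n, :n], 0.0)
    a_mat[n, :n] = 1.0
    a_mat[:n, n] = 1.0
    a_mat[n, n] = 0.0
    try:
        factor = lu_factor(a_mat)
    except Exception as exc:
        raise SingularSystemError(f"kriging system factorization failed: {exc}") from exc
    gx, gy = grid.nodes()
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    ddx = xy[:, 0][:, None] - nodes[:, 0][None, :]
    ddy = xy[:, 1][:, None] - nodes[:, 1][None, :]
    b = np.empty((n + 1, nodes.shape[0]))
    b[:n] = model.semivariance(ddx, ddy)
    # exact-interpolation convention: zero semivariance at coincident points
    b[:n][(ddx == 0) & (ddy == 0)] = 0.0
    b[n] = 1.0
    sol = lu_solve(factor, b)
    weights = sol[:n]
    preds = weights.T @ z
    variance = None
    if compute_variance:
        variance = np.einsum("ij,ij->j", sol, b).reshape(grid.ny, grid.nx)
        variance = np.maximum(variance, 0.0)
    if not np.all(np.isfinite(preds)):
        raise SingularSystemError("non-finite kriging predictions (singular system?)")
    return KrigedField(grid=grid, values=preds.reshape(grid.ny, grid.nx), variance=variance)


def ring_average(field: KrigedField, ring: RingSpec) -> tuple[float, float]:
    """Mean and sample SD of the field over nodes inside the circle."""
    gx, gy = field.grid.nodes()
    r = ring.diameter / 2.0
    inside = (gx - ring.center_x) ** 2 + (gy - ring.center_y) ** 2 <= r**2
    n_inside = int(inside.sum())
    if n_inside == 0:
        raise DomainError(
            f"no grid nodes inside ring at ({ring.center_x}, {ring.center_y}), "
            f"diameter {ring.diameter}; circle too small for the grid resolution"
        )
    vals = field.values[inside]
    sd = float(np.std(vals, ddof=1)) if n_inside > 1 else 0.0
    return float(vals.mean()), sd


# ---------------------------------------------------------------------------
# CSV interfaces

MEASUREMENT_COLUMNS = ["x_mm", "y_mm", "intensity_umol_m2_s"]
RING_COLUMNS = ["ring_id", "center_x_mm", "center_y_mm"]


def read_measurements_csv(path: str | Path) -> list[PARMeasurement]:
    df = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
    return [
        PARMeasurement(float(r.x_mm), float(r.y_mm), float(r.intensity_umol_m2_s))
        for r in df.itertuples()
    ]


def write_measurements_csv(measurements: Iterable[PARMeasurement], path: str | Path) -> None:
    pd.DataFrame(
        [(m.x, m.y, m.intensity) for m in measurements], columns=MEASUREMENT_COLUMNS
    ).to_csv(path, index=False)
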