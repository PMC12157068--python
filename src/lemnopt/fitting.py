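"""Least-squares parameter estimation from end-of-trial densities.

Each growth trial contributes one residual: observed minus predicted final
density.  The four free kinetic parameters are optimized in log space (which
enforces positivity) with a Nelder-Mead search from the supplied initial
estimates, followed by a Levenberg-Marquardt polish.  Standard errors come
from the Gauss-Newton Hessian approximation ``sigma^2 (J^T J)^-1`` with
p-values from a two-sided t reference on n - p degrees of freedom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares, minimize

from .errors import ConfigurationError, DomainError, IntegrationError, ZeroVarianceError
from .model_core import (
    DEFAULT_PHOTOPERIOD,
    GrowthParams,
    ModelParams,
    VanDyckParams,
    simulate,
    simulate_terminal_batch,
)

__all__ = [
    "TrialRecord",
    "LongTermSeries",
    "FitResult",
    "DEFAULT_INITIAL_ESTIMATES",
    "predict_final_density",
    "predict_final_densities",
    "fit",
    "r_squared",
    "validate_long_term",
    "read_trials_csv",
    "write_trials_csv",
    "read_longterm_csv",
    "write_longterm_csv",
]

ModelTag = Literal["developed", "vandyck"]

#: Initial parameter estimates used when the caller supplies none,
#: in the free-parameter order of each model.
DEFAULT_INITIAL_ESTIMATES: dict[str, tuple[float, ...]] = {
    "developed": (0.5, 0.05, 0.1, 20.0),  # r_phot_i, r_resp, eps_hat, k
    "vandyck": (0.2, 0.02, 70.0, 30.0),  # r_phot_i, r_resp, h_D, K_I
}

_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "developed": ("r_phot_i", "r_resp", "eps_hat", "k"),
    "vandyck": ("r_phot_i", "r_resp", "h_D", "K_I"),
}


@dataclass(frozen=True)
class TrialRecord:
    """One ring-subarea growth trial; the unit of the fit."""

    trial_id: str
    I_S: float
    D_0: float
    D_7: float
    duration: float = 7.0

    def __post_init__(self) -> None:
        if not self.D_0 > 0:
            raise ConfigurationError(f"{self.trial_id}: D_0 must be > 0")
        if not self.D_7 > 0:
            raise ConfigurationError(f"{self.trial_id}: D_7 must be > 0")
        if self.I_S < 0:
            raise ConfigurationError(f"{self.trial_id}: I_S must be >= 0")
        if self.duration < 0:
            raise ConfigurationError(f"{self.trial_id}: duration must be >= 0")


@dataclass(frozen=True)
class LongTermSeries:
    """Biweekly long-term density observations at one light intensity."""

    series_id: str
    I_S: float
    times: np.ndarray
    densities: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        dens = np.asarray(self.densities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "densities", dens)
        if times.ndim != 1 or dens.shape != times.shape:
            raise ConfigurationError("times/densities must be 1-D and equally long")
        if times[0] != 0 or np.any(np.diff(times) <= 0):
            raise ConfigurationError("times must be strictly increasing from 0")
        if np.any(dens <= 0):
            raise ConfigurationError("densities must be > 0")


@dataclass
class FitResult:
    """Outcome of a least-squares fit with uncertainty diagnostics."""

    model: str
    params: ModelParams
    estimates: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    rss: float
    r2: float
    converged: bool
    n_obs: int
    n_iter: int
    initial_estimates: tuple[float, ...]
    objective_trace: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "estimates": self.estimates,
            "std_errors": self.std_errors,
            "p_values": self.p_values,
            "E": self.params.E,
            "rss": self.rss,
            "r2": self.r2,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_iter": self.n_iter,
            "initial_estimates": list(self.initial_estimates),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, allow_nan=True))


def _params_from_vector(theta: np.ndarray, model: str, E: float) -> ModelParams:
    if model == "developed":
        return GrowthParams(*map(float, theta), E=E)
    if model == "vandyck":
        return VanDyckParams(*map(float, theta), E=E)
    raise ConfigurationError(f"unknown model tag {model!r}")


def predict_final_density(trial: TrialRecord, params: ModelParams) -> float:
    """Terminal density of the trial trajectory under the given parameters."""
    if trial.duration == 0:
        return trial.D_0
    try:
        traj = simulate(trial.D_0, trial.I_S, params, trial.duration)
    except IntegrationError as exc:
        raise IntegrationError(f"trial {trial.trial_id!r}: {exc}") from exc
    return traj.final_density


def predict_final_densities(trials: Sequence[TrialRecord], params: ModelParams) -> np.ndarray:
    """Vectorized terminal densities for a collection of trials.

    Trials sharing a duration are integrated together as one stacked ODE.
    """
    trials = list(trials)
    out = np.empty(len(trials))
    durations = {t.duration for t in trials}
    for dur in durations:
        idx = [i for i, t in enumerate(trials) if t.duration == dur]
        d0 = np.array([trials[i].D_0 for i in idx])
        i_s = np.array([trials[i].I_S for i in idx])
        if dur == 0:
            out[idx] = d0
        else:
            out[idx] = simulate_terminal_batch(d0, i_s, params, dur)
    return out


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (about the mean)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise DomainError("observed and predicted must be non-empty and equally long")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ZeroVarianceError("observations have zero variance; R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def fit(
    trials: Sequence[TrialRecord],
    model: ModelTag = "developed",
    initial_estimates: Sequence[float] | None = None,
    E: float = DEFAULT_PHOTOPERIOD,
    hessian: Literal["gauss-newton", "full"] = "gauss-newton",
) -> FitResult:
    """Estimate the four free kinetic parameters from trial final densities.

    ``E`` is held fixed, never estimated.  The objective trace (one entry
    per accepted Nelder-Mead iteration plus the final polished value) is
    non-increasing and exposed on the result for testing.
    """
    trials = list(trials)
    names = _PARAM_NAMES[model]
    if len(trials) < len(names):
        raise ConfigurationError(f"need at least {len(names)} trials, got {len(trials)}")
    x0 = tuple(
        DEFAULT_INITIAL_ESTIMATES[model] if initial_estimates is None else initial_estimates
    )
    if len(x0) != len(names) or any(v <= 0 for v in x0):
        raise ConfigurationError(f"initial estimates must be {len(names)} positive values")
    obs = np.array([t.D_7 for t in trials])

    def residuals_log(theta_log: np.ndarray) -> np.ndarray:
        params = _params_from_vector(np.exp(theta_log), model, E)
        return predict_final_densities(trials, params) - obs

    trace: list[float] = []

    def rss_log(theta_log: np.ndarray) -> float:
        r = residuals_log(theta_log)
        return float(r @ r)

    theta0 = np.log(np.asarray(x0, dtype=float))
    nm = minimize(
        rss_log,
        theta0,
        method="Nelder-Mead",
        callback=lambda xk: trace.append(rss_log(xk)),
        options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 2000, "maxfev": 4000},
    )
    ls = least_squares(residuals_log, nm.x, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    theta_hat = ls.x if 2 * ls.cost <= nm.fun else nm.x
    rss = min(2 * float(ls.cost), float(nm.fun))
    trace.append(rss)
    converged = bool(nm.success or ls.success)
    estimates = np.exp(theta_hat)
    params = _params_from_vector(estimates, model, E)

    n, p = len(trials), len(names)
    se = np.full(p, np.nan)
    pvals = np.full(p, np.nan)
    if n > p:
        sigma2 = rss / (n - p)
        # Jacobian w.r.t. natural-scale parameters via the chain rule.
        jac_nat = ls.jac / estimates[np.newaxis, :]
        if hessian == "full":
            hess = _finite_difference_hessian(
                lambda th: float(np.sum(residuals_log(np.log(th)) ** 2)), estimates
            )
            cov_core = hess / 2.0
        else:
            cov_core = jac_nat.T @ jac_nat
        try:
            cov = sigma2 * np.linalg.inv(cov_core)
            diag = np.diag(cov)
            if np.all(diag >= 0):
                se = np.sqrt(diag)
                tstat = estimates / se
                pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - p)
        except np.linalg.LinAlgError:
            pass  # singular J^T J: SEs stay NaN rather than fabricated

    pred = predict_final_densities(trials, params)
    return FitResult(
        model=model,
        params=params,
        estimates=dict(zip(names, map(float, estimates))),
        std_errors=dict(zip(names, map(float, se))),
        p_values=dict(zip(names, map(float, pvals))),
        rss=rss,
        r2=r_squared(obs, pred),
        converged=converged,
        n_obs=n,
        n_iter=int(nm.nit),
        initial_estimates=x0,
        objective_trace=trace,
    )


def _finite_difference_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function of positive params."""
    p = x.size
    h = rel_step * np.abs(x)
    hess = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                hess[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
            else:
                hess[i, j] = hess[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h[i] * h[j])
    return hess


def validate_long_term(series: LongTermSeries, params: ModelParams) -> float:
    """R^2 of fixed-parameter model predictions on a long-term series.

    The trajectory starts from the first observed density; no refitting.
    """
    return r_squared(series.densities, _densities_at(series, params))


def _densities_at(series: LongTermSeries, params: ModelParams) -> np.ndarray:
    """Model densities at the exact observation times of the series."""
    from scipy.integrate import solve_ivp

    from .model_core import _make_rhs

    rhs = _make_rhs(params, float(series.I_S))
    sol = solve_ivp(
        rhs,
        (0.0, float(series.times[-1])),
        [float(series.densities[0])],
        method="RK45",
        rtol=1e-8,
        atol=1e-10,
        t_eval=series.times,
    )
    if not sol.success:
        raise IntegrationError(f"series {series.series_id!r}: {sol.message}")
    return sol.y[0]


# ---------------------------------------------------------------------------
# CSV interfaces

TRIALS_COLUMNS = ["trial_id", "i_s_umol_m2_s", "d0_gdw_m2", "d7_gdw_m2", "duration_d"]
LONGTERM_COLUMNS = ["series_id", "i_s_umol_m2_s", "time_d", "density_gdw_m2"]


def read_trials_csv(path: str | Path) -> list[TrialRecord]:
    df = pd.read_csv(path)
    missing = set(TRIALS_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
    return [
        TrialRecord(
            trial_id=str(row.trial_id),
            I_S=float(row.i_s_umol_m2_s),
            D_0=float(row.d0_gdw_m2),
            D_7=float(row.d7_gdw_m2),
            duration=float(row.duration_d),
        )
        for row in df.itertuples()
    ]


def write_trials_csv(trials: Iterable[TrialRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(t.trial_id, t.I_S, t.D_0, t.D_7, t.duration) for t in trials],
        columns=TRIALS_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_longterm_csv(path: str | Path) -> list[LongTermSeries]:
    df = pd.read_csv(path)
    missing = set(LONGTERM_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for sid, grp in df.groupby("series_id", sort=False):
        grp = grp.sort_values("time_d")
        i_s = grp["i_s_umol_m2_s"].unique()
        if i_s.size != 1:
            raise ConfigurationError(f"series {sid!r}: multiple I_S values")
        out.append(
            LongTermSeries(
                series_id=str(sid),
                I_S=float(i_s[0]),
                times=grp["time_d"].to_numpy(float),
                densities=grp["density_gdw_m2"].to_numpy(float),
            )
        )
    return out


def write_longterm_csv(series: Iterable[LongTermSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for t, d in zip(s.times, s.densities):
            rows.append((s.series_id, s.I_S, t, d))
    pd.DataFrame(rows, columns=LONGTERM_COLUMNS).to_csv(path, index=False)
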