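"""Model calibration against longitudinal tumor-volume measurements.

Fitting minimizes the sum of relative squared differences between
simulated and measured volumes; goodness of fit is reported as RMSE.
The population growth rate is selected by a grid search over doubling
times, per-patient parameters (S, epsilon, V0) are estimated by
multistart bounded local optimization, and uncertainty is quantified by
a measurement-perturbation bootstrap.  Parameter-sharing alternatives
are ranked by the least-squares AIC, and a one-at-a-time perturbation
analysis ranks parameter sensitivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .model_core import ModelParams, evaluate_volumes

__all__ = [
    "Measurement",
    "FitConfig",
    "FitResult",
    "SharingConfig",
    "rmse",
    "relative_sq_objective",
    "fit_patient",
    "grid_search_lambda",
    "aic_compare",
    "bootstrap_fit",
    "sensitivity_rank",
    "default_lambda_grid",
]


@dataclass(frozen=True)
class Measurement:
    """One tumor-volume measurement: day relative to treatment start
    (day 0 = first fraction), volume in cm^3."""

    day: float
    volume: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.day) or not math.isfinite(self.volume):
            raise ValueError("measurement fields must be finite")
        if self.volume < 0:
            raise ValueError("volume must be non-negative")


def default_lambda_grid() -> np.ndarray:
    """Growth-rate grid from doubling times of 5-40 days in 1-day steps."""
    doubling_days = np.arange(5, 41)
    return np.sort(math.log(2.0) / doubling_days)


@dataclass
class FitConfig:
    """Bounds, grid, optimizer and bootstrap settings for calibration."""

    lambda_bounds: tuple[float, float] = (0.017, 0.14)
    epsilon_bounds: tuple[float, float] = (0.0, 0.1)
    s_bounds: tuple[float, float] = (0.0, 1.0)
    v0_rel_bounds: tuple[float, float] = (0.7, 1.3)
    gamma0_bounds: tuple[float, float] = (0.0, 0.14)
    objective_floor: float = 0.5
    #: positive lower limit used for the internal log-epsilon parametrization
    epsilon_log_floor: float = 1e-7
    lambda_grid: np.ndarray = field(default_factory=default_lambda_grid)
    n_starts: int = 8
    n_starts_refit: int = 4
    step_tol: float = 1e-12
    optimality_tol: float = 1e-9
    three_term_grid_score: bool = False
    n_bootstrap: int = 50
    noise_sd_rel: float = 0.2
    small_volume_cut: float = 2.0
    small_volume_sd: float = 0.5
    seed: int = 0


@dataclass
class FitResult:
    params: ModelParams
    rmse: float
    objective: float
    converged: bool
    bootstrap_ensemble: np.ndarray | None = None  # shape (n_reps, 2): (S, eps)


def rmse(measured: Sequence[float], simulated: Sequence[float]) -> float:
    """Root mean squared error between measured and simulated volumes."""
    measured = np.asarray(measured, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if measured.shape != simulated.shape or measured.size == 0:
        raise ValueError("measured and simulated must have equal non-zero length")
    return float(np.sqrt(np.mean((measured - simulated) ** 2)))


def relative_sq_objective(
    measured: Sequence[float],
    simulated: Sequence[float],
    floor: float = 0.5,
) -> float:
    """Sum of squared relative differences, with the denominator floored
    to handle zero or near-zero measured volumes."""
    measured = np.asarray(measured, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if measured.shape != simulated.shape or measured.size == 0:
        raise ValueError("measured and simulated must have equal non-zero length")
    if floor <= 0:
        raise ValueError("floor must be positive")
    denom = np.maximum(measured, floor)
    return float(np.sum(((simulated - measured) / denom) ** 2))


def _measurement_arrays(measurements: Sequence[Measurement]) -> tuple[np.ndarray, np.ndarray]:
    days = np.array([m.day for m in measurements], dtype=float)
    vols = np.array([m.volume for m in measurements], dtype=float)
    order = np.argsort(days)
    return days[order], vols[order]


def _baseline_volume(days: np.ndarray, vols: np.ndarray) -> float:
    pre = days <= 0
    if not np.any(pre):
        raise ValueError("at least one measurement at day <= 0 is required")
    return float(vols[pre][-1])


def _eps_to_u(eps: float, floor: float) -> float:
    return math.log10(max(eps, floor))


def _u_to_eps(u: float, floor: float) -> float:
    eps = 10.0**u
    return 0.0 if eps <= floor else eps


def _multistart_minimize(objective, bounds, n_starts, seed, extra_starts=()):
    """Bounded local minimization from Latin-hypercube starts plus any
    caller-provided starts; returns (best_x, best_fun, success)."""
    bounds = np.asarray(bounds, dtype=float)
    dim = len(bounds)
    sampler = qmc.LatinHypercube(d=dim, seed=seed)
    unit = sampler.random(n=max(n_starts, 1))
    starts = [bounds[:, 0] + u * (bounds[:, 1] - bounds[:, 0]) for u in unit]
    starts = list(extra_starts) + starts
    best_x, best_fun, success = None, np.inf, False
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), bounds[:, 0], bounds[:, 1])
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500},
        )
        if res.fun < best_fun:
            best_x, best_fun, success = res.x, float(res.fun), bool(res.success)
    return best_x, best_fun, success


def _simulated_at(params: ModelParams, fraction_times, days: np.ndarray) -> np.ndarray:
    vl, vd = evaluate_volumes(params, fraction_times, days)
    return vl + vd


def fit_patient(
    measurements: Sequence[Measurement],
    lambda_growth: float,
    fraction_times: Sequence[float],
    config: FitConfig | None = None,
) -> FitResult:
    """Fit (S, epsilon, V0) for one patient with a caller-fixed growth
    rate and gamma0 = lambda.

    epsilon is optimized on a log10 scale over the positive part of its
    bound interval; values at the internal floor are reported as 0.
    """
    config = config or FitConfig()
    if len(measurements) < 4:
        raise ValueError("at least 4 measurements are required to fit 3 parameters")
    days, vols = _measurement_arrays(measurements)
    if np.all(vols == 0):
        raise ValueError("all measured volumes are zero")
    baseline = _baseline_volume(days, vols)
    if baseline <= 0:
        raise ValueError("baseline volume must be positive")
    fraction_times = np.asarray(fraction_times, dtype=float)

    v0_lo = baseline * config.v0_rel_bounds[0]
    v0_hi = baseline * config.v0_rel_bounds[1]
    u_lo = math.log10(max(config.epsilon_bounds[0], config.epsilon_log_floor))
    u_hi = math.log10(config.epsilon_bounds[1])
    bounds = [config.s_bounds, (u_lo, u_hi), (v0_lo, v0_hi)]

    def objective(theta: np.ndarray) -> float:
        s, u, v0 = theta
        params = ModelParams(
            lambda_growth=lambda_growth,
            surviving_fraction=float(s),
            epsilon=10.0 ** float(u),
            gamma0=lambda_growth,
            V0=float(v0),
        )
        sim = _simulated_at(params, fraction_times, days)
        return relative_sq_objective(vols, sim, config.objective_floor)

    heuristic = [0.5, 0.5 * (u_lo + u_hi), float(np.clip(baseline, v0_lo, v0_hi))]
    best_x, best_fun, success = _multistart_minimize(
        objective, bounds, config.n_starts, config.seed, extra_starts=[heuristic]
    )
    s_hat, u_hat, v0_hat = best_x
    eps_hat = _u_to_eps(float(u_hat), config.epsilon_log_floor)
    params = ModelParams(
        lambda_growth=lambda_growth,
        surviving_fraction=float(s_hat),
        epsilon=eps_hat,
        gamma0=lambda_growth,
        V0=float(v0_hat),
    )
    sim = _simulated_at(params, fraction_times, days)
    return FitResult(
        params=params,
        rmse=rmse(vols, sim),
        objective=best_fun,
        converged=success,
    )


def _grid_score(rmses: np.ndarray, three_term: bool) -> float:
    terms = [float(np.mean(rmses)), float(np.median(rmses)), float(np.max(rmses))]
    if not three_term:
        terms.append(float(np.min(rmses)))
    return float(sum(terms))


def grid_search_lambda(
    cohort: Sequence[tuple[Sequence[Measurement], Sequence[float]]],
    lambda_grid: Sequence[float] | None = None,
    config: FitConfig | None = None,
) -> tuple[float, pd.DataFrame]:
    """Select the population growth rate minimizing the summary score of
    per-patient RMSEs (sum of mean, median, minimum and maximum by
    default; a three-term variant drops the minimum)."""
    config = config or FitConfig()
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    grid = np.asarray(
        lambda_grid if lambda_grid is not None else config.lambda_grid, dtype=float
    )
    if grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    records = []
    for lam in grid:
        rmses = np.array(
            [
                fit_patient(meas, lam, frac, config).rmse
                for meas, frac in cohort
            ]
        )
        records.append(
            {
                "lambda": float(lam),
                "rmse_mean": float(np.mean(rmses)),
                "rmse_median": float(np.median(rmses)),
                "rmse_min": float(np.min(rmses)),
                "rmse_max": float(np.max(rmses)),
                "score": _grid_score(rmses, config.three_term_grid_score),
            }
        )
    table = pd.DataFrame.from_records(records)
    best = float(table.loc[table["score"].idxmin(), "lambda"])
    return best, table


@dataclass(frozen=True)
class SharingConfig:
    """Which parameters are shared across the cohort.

    ``global_lambda`` makes the growth rate population-wide (selected on
    the fitting grid); ``tie_gamma0`` constrains gamma0 = lambda; all
    other parameters (epsilon, S, V0) are always patient-specific.
    """

    name: str
    global_lambda: bool = False
    tie_gamma0: bool = False

    def k_free(self, n_patients: int) -> int:
        per_patient = 3  # epsilon, S, V0
        if not self.global_lambda:
            per_patient += 1
        if not self.tie_gamma0:
            per_patient += 1
        k = per_patient * n_patients + (1 if self.global_lambda else 0)
        if k == 0:
            raise ValueError("sharing config must leave free parameters")
        return k


def _fit_free(
    measurements: Sequence[Measurement],
    fraction_times: Sequence[float],
    config: FitConfig,
    lambda_fixed: float | None,
    tie_gamma0: bool,
) -> tuple[ModelParams, float]:
    """Fit one patient with optionally free lambda and gamma0; returns
    (params, absolute RSS)."""
    days, vols = _measurement_arrays(measurements)
    baseline = _baseline_volume(days, vols)
    fraction_times = np.asarray(fraction_times, dtype=float)
    u_lo = math.log10(max(config.epsilon_bounds[0], config.epsilon_log_floor))
    u_hi = math.log10(config.epsilon_bounds[1])
    bounds = [
        config.s_bounds,
        (u_lo, u_hi),
        (baseline * config.v0_rel_bounds[0], baseline * config.v0_rel_bounds[1]),
    ]
    free_lambda = lambda_fixed is None
    if free_lambda:
        bounds.append(config.lambda_bounds)
    if not tie_gamma0:
        bounds.append(config.gamma0_bounds)

    def unpack(theta: np.ndarray) -> ModelParams:
        s, u, v0 = theta[:3]
        i = 3
        lam = float(theta[i]) if free_lambda else float(lambda_fixed)
        if free_lambda:
            i += 1
        gamma0 = lam if tie_gamma0 else float(theta[i])
        return ModelParams(
            lambda_growth=lam,
            surviving_fraction=float(s),
            epsilon=10.0 ** float(u),
            gamma0=gamma0,
            V0=float(v0),
        )

    def objective(theta: np.ndarray) -> float:
        sim = _simulated_at(unpack(theta), fraction_times, days)
        return relative_sq_objective(vols, sim, config.objective_floor)

    best_x, _, _ = _multistart_minimize(objective, bounds, config.n_starts, config.seed)
    params = unpack(best_x)
    sim = _simulated_at(params, fraction_times, days)
    rss = float(np.sum((vols - sim) ** 2))
    return params, rss


def aic_compare(
    cohort: Sequence[tuple[Sequence[Measurement], Sequence[float]]],
    sharing_configs: Sequence[SharingConfig],
    config: FitConfig | None = None,
    lambda_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Rank parameter-sharing alternatives by least-squares AIC,
    n*ln(RSS/n) + 2k, with residuals pooled over the whole cohort."""
    config = config or FitConfig()
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    grid = np.asarray(
        lambda_grid if lambda_grid is not None else config.lambda_grid, dtype=float
    )
    n_total = int(sum(len(meas) for meas, _ in cohort))
    rows = []
    for sc in sharing_configs:
        k = sc.k_free(len(cohort))
        if sc.global_lambda:
            best_rss = np.inf
            for lam in grid:
                rss = sum(
                    _fit_free(meas, frac, config, lam, sc.tie_gamma0)[1]
                    for meas, frac in cohort
                )
                best_rss = min(best_rss, rss)
            rss = best_rss
        else:
            rss = sum(
                _fit_free(meas, frac, config, None, sc.tie_gamma0)[1]
                for meas, frac in cohort
            )
        rss = max(float(rss), 1e-300)
        aic = n_total * math.log(rss / n_total) + 2 * k
        rows.append({"name": sc.name, "aic": aic, "rss": rss, "k": k, "n": n_total})
    table = pd.DataFrame.from_records(rows).sort_values("aic").reset_index(drop=True)
    return table


def perturb_volumes(
    volumes: np.ndarray,
    rng: np.random.Generator,
    noise_sd_rel: float,
    small_volume_cut: float,
    small_volume_sd: float,
) -> np.ndarray:
    """One bootstrap replicate of the measurement noise model:
    multiplicative N(1, sd^2) noise for volumes at or above the cut,
    additive N(0, sd_small^2) below it, negatives clamped to zero."""
    volumes = np.asarray(volumes, dtype=float)
    out = np.empty_like(volumes)
    large = volumes >= small_volume_cut
    out[large] = volumes[large] * rng.normal(1.0, noise_sd_rel, size=int(large.sum()))
    small = ~large
    out[small] = volumes[small] + rng.normal(0.0, small_volume_sd, size=int(small.sum()))
    return np.maximum(out, 0.0)


def bootstrap_fit(
    measurements: Sequence[Measurement],
    point_fit: FitResult,
    fraction_times: Sequence[float],
    n_reps: int = 50,
    noise_sd_rel: float = 0.2,
    small_volume_cut: float = 2.0,
    small_volume_sd: float = 0.5,
    seed: int = 0,
    config: FitConfig | None = None,
) -> np.ndarray:
    """Refit (S, epsilon) on noise-perturbed measurement replicates with
    V0 and lambda held at the point fit; returns an (n_reps, 2) array of
    (S, epsilon) pairs."""
    config = config or FitConfig()
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    days, vols = _measurement_arrays(measurements)
    fraction_times = np.asarray(fraction_times, dtype=float)
    rng = np.random.default_rng(seed)
    lam = point_fit.params.lambda_growth
    v0 = point_fit.params.V0
    u_lo = math.log10(max(config.epsilon_bounds[0], config.epsilon_log_floor))
    u_hi = math.log10(config.epsilon_bounds[1])
    bounds = [config.s_bounds, (u_lo, u_hi)]
    point_start = [
        point_fit.params.surviving_fraction,
        _eps_to_u(point_fit.params.epsilon, config.epsilon_log_floor),
    ]
    ensemble = np.empty((n_reps, 2))
    for rep in range(n_reps):
        rep_vols = perturb_volumes(
            vols, rng, noise_sd_rel, small_volume_cut, small_volume_sd
        )

        def objective(theta: np.ndarray) -> float:
            s, u = theta
            params = ModelParams(
                lambda_growth=lam,
                surviving_fraction=float(s),
                epsilon=10.0 ** float(u),
                gamma0=lam,
                V0=v0,
            )
            sim = _simulated_at(params, fraction_times, days)
            return relative_sq_objective(rep_vols, sim, config.objective_floor)

        best_x, _, _ = _multistart_minimize(
            objective,
            bounds,
            config.n_starts_refit,
            seed=int(rng.integers(0, 2**31 - 1)),
            extra_starts=[point_start],
        )
        s_hat, u_hat = best_x
        ensemble[rep] = (
            float(s_hat),
            _u_to_eps(float(u_hat), config.epsilon_log_floor),
        )
    return ensemble


def sensitivity_rank(
    params: ModelParams,
    measurements: Sequence[Measurement],
    fraction_times: Sequence[float],
    perturbation: float = 0.2,
    config: FitConfig | None = None,
) -> list[tuple[str, float, bool]]:
    """Rank the patient-specific parameters (S, epsilon, V0) by the
    normalized RMSE between perturbed and nominal trajectories.

    Each parameter is perturbed by +/- the given fraction (clipped to its
    bounds, with a flag when clipping occurred); the larger of the two
    directional scores is kept and parameters are returned in descending
    order of sensitivity."""
    if perturbation < 0:
        raise ValueError("perturbation must be non-negative")
    config = config or FitConfig()
    days, _ = _measurement_arrays(measurements)
    fraction_times = np.asarray(fraction_times, dtype=float)
    nominal = _simulated_at(params, fraction_times, days)
    norm = float(np.mean(nominal))
    param_bounds = {
        "surviving_fraction": config.s_bounds,
        "epsilon": config.epsilon_bounds,
        "V0": (1e-12, np.inf),
    }
    results = []
    for name in ("surviving_fraction", "epsilon", "V0"):
        base = getattr(params, name)
        score, clipped = 0.0, False
        for sign in (-1.0, 1.0):
            value = base * (1.0 + sign * perturbation)
            lo, hi = param_bounds[name]
            clipped_value = float(np.clip(value, lo, hi))
            clipped = clipped or clipped_value != value
            perturbed = replace(params, **{name: clipped_value})
            sim = _simulated_at(perturbed, fraction_times, days)
            score = max(score, rmse(nominal, sim) / norm)
        results.append((name, score, clipped))
    results.sort(key=lambda r: r[1], reverse=True)
    return results
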