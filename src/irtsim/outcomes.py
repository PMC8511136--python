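"""Time-to-event scoring and supporting statistics for arm comparisons.

Scores the time for a simulated trajectory to reach a cutoff volume,
builds Kaplan-Meier curves and logrank comparisons, classifies patients
into four response groups, and provides rank-sum, Pearson-correlation
and generalized-equivalent-uniform-dose (gEUD) helpers.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .model_core import Trajectory

__all__ = [
    "SurvivalRecord",
    "DoseVolumeHistogram",
    "time_to_cutoff",
    "km_estimate",
    "logrank_test",
    "ranksum_test",
    "signed_rank_test",
    "pearson_corr",
    "geud",
    "classify_group",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """Per-patient, per-arm time-to-event entry; censored records carry
    the horizon as their time."""

    patient_id: str
    time: float
    event: bool
    arm: str = ""

    def __post_init__(self) -> None:
        if self.time < 0 or not math.isfinite(self.time):
            raise ValueError("time must be finite and non-negative")


@dataclass(frozen=True)
class DoseVolumeHistogram:
    """Differential DVH as (dose Gy, fractional volume) bins."""

    doses: tuple[float, ...]
    fractional_volumes: tuple[float, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        v = np.asarray(self.fractional_volumes, dtype=float)
        if d.shape != v.shape or d.size == 0:
            raise ValueError("doses and fractional_volumes must match and be non-empty")
        if np.any(v < 0):
            raise ValueError("fractional volumes must be non-negative")
        if abs(float(v.sum()) - 1.0) > 1e-6:
            raise ValueError("fractional volumes must sum to 1")


_CROSS_SCAN_STEP = 0.25
_CROSS_TOL = 1e-3


def _first_crossing(volume_fn, lo: float, hi: float, threshold: float) -> float | None:
    """First upcrossing of ``threshold`` on (lo, hi], found by a
    fixed-step vectorized scan followed by bisection; None if none.
    ``volume_fn`` maps an array of times to an array of volumes."""
    grid = np.arange(lo, hi, _CROSS_SCAN_STEP)
    grid = np.append(grid, hi)
    vols = np.asarray(volume_fn(grid))
    above = vols >= threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(grid[0])
    a, b = float(grid[i - 1]), float(grid[i])
    while b - a > _CROSS_TOL:
        mid = 0.5 * (a + b)
        if float(volume_fn(np.array([mid]))[0]) >= threshold:
            b = mid
        else:
            a = mid
    return float(b)


def time_to_cutoff(
    trajectory: Trajectory,
    cutoff_volume: float | None,
    fallback_fraction: float = 1.2,
    horizon: float | None = None,
    patient_id: str = "",
    arm: str = "",
) -> SurvivalRecord:
    """Time for the total volume to first reach the cutoff.

    With no usable cutoff the threshold falls back to
    ``fallback_fraction`` times the pre-treatment volume.  The crossing
    is located segment-by-segment on the piecewise-analytic trajectory;
    records are censored at the horizon when the threshold is never
    reached.  Times are relative to treatment start.
    """
    params = trajectory.params
    if cutoff_volume is None or cutoff_volume <= 0:
        if fallback_fraction is None or fallback_fraction <= 0:
            raise ValueError("cutoff_volume must be positive or a fallback given")
        threshold = fallback_fraction * params.V0
    else:
        threshold = float(cutoff_volume)
    if horizon is None:
        horizon = float(trajectory.times[-1])

    if params.V0 >= threshold:
        return SurvivalRecord(patient_id, 0.0, True, arm)

    fraction_times = np.asarray(trajectory.fraction_times, dtype=float)
    boundaries = [params.t0]
    boundaries += [float(t) for t in fraction_times if params.t0 < t < horizon]
    boundaries.append(float(horizon))

    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        if hi <= lo:
            continue
        # evaluate strictly inside the segment so fraction-time ties
        # resolve to the post-fraction branch
        crossing = _first_crossing(
            trajectory.volume_at, lo + 1e-9, hi, threshold
        )
        if crossing is not None:
            return SurvivalRecord(patient_id, crossing - params.t0, True, arm)
    return SurvivalRecord(patient_id, float(horizon) - params.t0, False, arm)


def km_estimate(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Product-limit survival estimate as a (time, survival, at_risk)
    step table starting at survival 1."""
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    times = [r.time for r in records]
    events = [r.event for r in records]
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(surv.index).ffill()
    return pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.iloc[:, 0].to_numpy(dtype=float),
            "at_risk": at_risk.to_numpy(dtype=float),
        }
    )


def logrank_test(
    groupA: Sequence[SurvivalRecord], groupB: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group logrank chi-square (1 df) and its upper-tail p-value."""
    if len(groupA) == 0 or len(groupB) == 0:
        raise ValueError("both groups must be non-empty")
    if not any(r.event for r in itertools.chain(groupA, groupB)):
        warnings.warn("no events in either group; logrank undefined, p = 1")
        return 0.0, 1.0
    res = _ll_logrank(
        [r.time for r in groupA],
        [r.time for r in groupB],
        event_observed_A=[r.event for r in groupA],
        event_observed_B=[r.event for r in groupB],
    )
    stat = float(res.test_statistic)
    if not math.isfinite(stat):
        return 0.0, 1.0
    return stat, float(res.p_value)


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumeration of all group
    assignments of the combined sample (midranks for ties)."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    n, m = len(x), len(y)
    w_obs = float(ranks[:n].sum())
    mu = n * (len(combined) + 1) / 2.0
    dev_obs = abs(w_obs - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(combined)), n):
        w = float(ranks[list(idx)].sum())
        if abs(w - mu) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return w_obs, count / total


def ranksum_test(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided two-sample rank-sum test.

    Uses exact enumeration when the combined sample size is at most 10,
    otherwise the tie-corrected normal approximation.  The returned
    statistic is the rank sum of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if x.size + y.size <= 10:
        return _exact_ranksum_p(x, y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = float(ranks[: x.size].sum())
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return w, float(res.pvalue)


def signed_rank_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test for equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("paired samples must be non-empty and equal length")
    res = stats.wilcoxon(x, y)
    return float(res.statistic), float(res.pvalue)


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("samples must be equal length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def geud(dvh: DoseVolumeHistogram, exponent: float = -10.0) -> float:
    """Generalized equivalent uniform dose, (sum v_i * D_i^a)^(1/a)."""
    if exponent == 0:
        raise ValueError("exponent must be non-zero")
    d = np.asarray(dvh.doses, dtype=float)
    v = np.asarray(dvh.fractional_volumes, dtype=float)
    active = v > 0
    if exponent < 0 and np.any(d[active] <= 0):
        raise ValueError("zero dose with negative exponent is undefined")
    return float(np.sum(v[active] * d[active] ** exponent) ** (1.0 / exponent))


def classify_group(
    tau_hfsrt: float,
    tau_irt: float,
    tau_boost: float,
    tolerance: float = 1.0,
) -> int:
    """Response-group label from the three per-arm times to cutoff.

    Group 1: boosted intermittent RT is still worse than HFSRT.
    Group 2: intermittent RT is worse but the boost compensates.
    Group 3: the boost extends beyond intermittent RT alone.
    Group 4: intermittent RT alone is best (boost adds nothing).
    Comparisons use the given tolerance in days; exact ties across all
    arms resolve to Group 4.
    """
    def lt(a: float, b: float) -> bool:
        return a < b - tolerance

    if lt(tau_boost, tau_hfsrt):
        return 1
    if lt(tau_irt, tau_hfsrt):
        return 2
    if lt(tau_irt, tau_boost):
        return 3
    return 4
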