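"""Counterfactual fractionation schedules and their simulation.

Builds hypofractionated (daily) and intermittent schedules, detects
volumetric progression at periodic assessments (volume exceeding the
running nadir by more than 20%), and simulates each schedule under a
patient's fitted parameters, optionally inserting a three-fraction boost
at the first detected progression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model_core import ModelParams, Trajectory, evaluate_volumes, simulate_trajectory

__all__ = [
    "Schedule",
    "SimOutcome",
    "make_hfsrt",
    "make_irt",
    "detect_progression",
    "simulate_arm",
    "compare_protocols",
    "PROGRESSION_FACTOR",
]

#: Progression is declared when an assessed volume exceeds the running
#: nadir by more than this factor.
PROGRESSION_FACTOR = 1.2


@dataclass(frozen=True)
class Schedule:
    """Planned fraction times plus assessment cadence and boost policy."""

    fraction_times: tuple[float, ...]
    assessment_interval: float = 42.0
    boost_enabled: bool = False
    boost_fraction_count: int = 3
    boost_spacing: float = 1.0
    horizon: float = 1500.0
    allow_repeat_boost: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.fraction_times, dtype=float)
        if times.size and np.any(np.diff(times) < 0):
            raise ValueError("fraction_times must be non-decreasing")
        if self.assessment_interval <= 0:
            raise ValueError("assessment_interval must be positive")
        if times.size and self.horizon <= times[-1]:
            raise ValueError("horizon must exceed the last planned fraction")


@dataclass
class SimOutcome:
    """Result of simulating one schedule for one parameter set."""

    schedule: Schedule
    trajectory: Trajectory
    assessment_days: np.ndarray
    assessment_volumes: np.ndarray
    progression_day: float | None
    boost_start_day: float | None
    fractions_delivered: int
    delivered_fraction_times: np.ndarray


def make_hfsrt(t0: float = 0.0, n_fractions: int = 5, **kwargs) -> Schedule:
    """Daily consecutive fractions starting at t0 (default five)."""
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    times = tuple(t0 + float(k) for k in range(n_fractions))
    kwargs.setdefault("name", f"hfsrt{n_fractions}")
    return Schedule(fraction_times=times, **kwargs)


def make_irt(
    t0: float = 0.0,
    interval: float = 42.0,
    n_fractions: int = 5,
    boost: bool = False,
    **kwargs,
) -> Schedule:
    """Intermittent single fractions every ``interval`` days from t0."""
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    if interval <= 0:
        raise ValueError("interval must be positive")
    times = tuple(t0 + k * float(interval) for k in range(n_fractions))
    kwargs.setdefault(
        "name", f"irt{n_fractions}_{int(interval)}d" + ("_boost" if boost else "")
    )
    return Schedule(fraction_times=times, boost_enabled=boost, **kwargs)


def detect_progression(
    assessment_volumes: Sequence[tuple[float, float]],
) -> float | None:
    """First assessment day whose volume exceeds the running minimum of
    all earlier assessments (baseline included) by more than 20%."""
    if len(assessment_volumes) == 0:
        raise ValueError("assessment_volumes must be non-empty")
    running_min = math.inf
    for day, volume in assessment_volumes:
        if running_min < math.inf and volume > PROGRESSION_FACTOR * running_min:
            return float(day)
        running_min = min(running_min, volume)
    return None


def _volume_at(params: ModelParams, fraction_times: np.ndarray, t: float) -> float:
    vl, vd = evaluate_volumes(params, fraction_times, [t])
    return float(vl[0] + vd[0])


def simulate_arm(params: ModelParams, schedule: Schedule) -> SimOutcome:
    """Simulate one schedule, assessing the (pre-fraction) volume every
    assessment interval and, when the boost policy is enabled, inserting
    three daily fractions starting at the first progression assessment.

    Scheduled fractions falling on a boost day are still delivered (the
    scheduled fraction first); intermittent fractions after a boost stay
    on their planned days.  By default at most one boost is delivered.
    """
    t0 = params.t0
    fractions = sorted(t for t in schedule.fraction_times if t <= schedule.horizon)
    n_assess = int(math.floor((schedule.horizon - t0) / schedule.assessment_interval))
    assessment_days = [t0 + k * schedule.assessment_interval for k in range(n_assess + 1)]
    if schedule.boost_enabled and not assessment_days:
        raise ValueError("boost requires at least one assessment")

    assessed: list[tuple[float, float]] = []
    progression_day: float | None = None
    boost_starts: list[float] = []
    running_min = math.inf
    frac_arr = np.asarray(fractions, dtype=float)
    for day in assessment_days:
        volume = _volume_at(params, frac_arr, day)
        assessed.append((day, volume))
        progressed = running_min < math.inf and volume > PROGRESSION_FACTOR * running_min
        running_min = min(running_min, volume)
        if progressed:
            if progression_day is None:
                progression_day = day
            may_boost = schedule.boost_enabled and (
                not boost_starts or schedule.allow_repeat_boost
            )
            if may_boost:
                boost_days = [
                    day + j * schedule.boost_spacing
                    for j in range(schedule.boost_fraction_count)
                    if day + j * schedule.boost_spacing <= schedule.horizon
                ]
                fractions = sorted(fractions + boost_days)
                frac_arr = np.asarray(fractions, dtype=float)
                boost_starts.append(day)

    eval_times = np.arange(t0, schedule.horizon + 0.5, 1.0)
    trajectory = simulate_trajectory(params, frac_arr, eval_times)
    assessed_arr = np.asarray(assessed, dtype=float)
    return SimOutcome(
        schedule=schedule,
        trajectory=trajectory,
        assessment_days=assessed_arr[:, 0],
        assessment_volumes=assessed_arr[:, 1],
        progression_day=progression_day,
        boost_start_day=boost_starts[0] if boost_starts else None,
        fractions_delivered=len(fractions),
        delivered_fraction_times=frac_arr,
    )


def compare_protocols(
    params: ModelParams, protocol_set: Sequence[Schedule]
) -> list[SimOutcome]:
    """Simulate every protocol under identical parameters."""
    if len(protocol_set) == 0:
        raise ValueError("protocol_set must be non-empty")
    return [simulate_arm(params, schedule) for schedule in protocol_set]
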