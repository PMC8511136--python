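"""Two-compartment tumor growth-response model with discrete radiation fractions.

The observed tumor volume is the sum of a viable compartment and a dying
compartment.  The viable compartment grows exponentially at rate
``lambda_growth`` and is depleted by a drug-kill rate ``gamma(t)`` that
itself decays exponentially at rate ``epsilon`` as resistance develops.
Each radiation fraction instantaneously moves a proportion ``1 - S`` of
the viable compartment into the dying compartment, which then shrinks
exponentially at the growth rate.  Between fractions both compartments
follow exact closed forms, so trajectories are piecewise analytic rather
than numerically integrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EPSILON_SWITCH",
    "ModelParams",
    "TumorState",
    "Trajectory",
    "live_volume_analytic",
    "dead_volume_decay",
    "apply_fraction",
    "evaluate_volumes",
    "simulate_trajectory",
    "doubling_time",
]

#: Below this resistance-decay rate the analytic limit branch is used.
EPSILON_SWITCH = 1e-12


def doubling_time(lambda_growth: float) -> float:
    """Volume doubling time (days) under pure exponential growth."""
    if lambda_growth <= 0:
        raise ValueError("growth rate must be positive")
    return math.log(2.0) / lambda_growth


@dataclass(frozen=True)
class ModelParams:
    """Model parameters: growth rate, radiation surviving fraction,
    resistance-decay rate, initial drug-kill rate, pre-treatment volume,
    and treatment start time (all rates in day^-1, volumes in cm^3).
    """

    lambda_growth: float
    surviving_fraction: float
    epsilon: float
    gamma0: float
    V0: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "lambda_growth",
            "surviving_fraction",
            "epsilon",
            "gamma0",
            "V0",
            "t0",
        ):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
        if self.lambda_growth <= 0:
            raise ValueError("lambda_growth must be positive")
        if not 0.0 <= self.surviving_fraction <= 1.0:
            raise ValueError("surviving_fraction must be in [0, 1]")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.gamma0 < 0:
            raise ValueError("gamma0 must be non-negative")
        if self.V0 <= 0:
            raise ValueError("V0 must be positive")

    def gamma_at(self, t: float) -> float:
        """Drug-kill rate at time ``t``; decays on the global clock from t0."""
        if t < self.t0:
            return 0.0
        return self.gamma0 * math.exp(-self.epsilon * (t - self.t0))


@dataclass(frozen=True)
class TumorState:
    """Snapshot of the two compartments at one time point."""

    t: float
    V_live: float
    V_dead: float

    def __post_init__(self) -> None:
        if self.V_live < 0 or self.V_dead < 0:
            raise ValueError("compartment volumes must be non-negative")

    @property
    def V_total(self) -> float:
        return self.V_live + self.V_dead


def _check_finite(*values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"non-finite input {v!r}")


def live_volume_analytic(
    V_live_ref: float,
    gamma_ref: float,
    params: ModelParams,
    t_ref: float,
    t: float,
) -> float:
    """Viable volume at time ``t`` given a reference state at ``t_ref``.

    ``gamma_ref`` is the drug-kill rate at the reference time.  For
    ``epsilon`` below :data:`EPSILON_SWITCH` the constant-kill limit is
    used instead of the 1/epsilon form.
    """
    _check_finite(V_live_ref, gamma_ref, t_ref, t)
    if t < t_ref:
        raise ValueError("evaluation time precedes reference time")
    if gamma_ref < 0:
        raise ValueError("gamma_ref must be non-negative")
    dt = t - t_ref
    lam = params.lambda_growth
    eps = params.epsilon
    if eps < EPSILON_SWITCH:
        exponent = (lam - gamma_ref) * dt
    else:
        exponent = lam * dt + (gamma_ref / eps) * math.expm1(-eps * dt)
    return V_live_ref * math.exp(exponent)


def dead_volume_decay(V_dead_ref: float, lambda_growth: float, dt: float) -> float:
    """Dying-compartment volume after ``dt`` days of exponential clearance."""
    _check_finite(V_dead_ref, lambda_growth, dt)
    if dt < 0:
        raise ValueError("dt must be non-negative")
    return V_dead_ref * math.exp(-lambda_growth * dt)


def apply_fraction(state: TumorState, surviving_fraction: float) -> TumorState:
    """Instantaneous effect of one radiation fraction: a proportion
    ``1 - S`` of the viable compartment moves to the dying compartment.
    Total volume is conserved at the fraction instant."""
    if not 0.0 <= surviving_fraction <= 1.0:
        raise ValueError("surviving_fraction must be in [0, 1]")
    killed = (1.0 - surviving_fraction) * state.V_live
    return TumorState(
        t=state.t,
        V_live=surviving_fraction * state.V_live,
        V_dead=state.V_dead + killed,
    )


def _validate_fraction_times(params: ModelParams, fraction_times: np.ndarray) -> None:
    if fraction_times.size == 0:
        return
    if np.any(np.diff(fraction_times) < 0):
        raise ValueError("fraction_times must be non-decreasing")
    if fraction_times[0] < params.t0:
        raise ValueError("fraction times must not precede t0")


def _reference_states(
    params: ModelParams, fraction_times: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Post-event reference states: the pre-treatment state at t0 followed
    by the post-fraction state at every fraction time (duplicate fraction
    times are applied sequentially)."""
    ref_t = [params.t0]
    ref_vl = [params.V0]
    ref_vd = [0.0]
    vl, vd, t_prev = params.V0, 0.0, params.t0
    for tf in fraction_times:
        gamma_ref = params.gamma_at(t_prev)
        vl = live_volume_analytic(vl, gamma_ref, params, t_prev, tf)
        vd = dead_volume_decay(vd, params.lambda_growth, tf - t_prev)
        vd = vd + (1.0 - params.surviving_fraction) * vl
        vl = params.surviving_fraction * vl
        ref_t.append(tf)
        ref_vl.append(vl)
        ref_vd.append(vd)
        t_prev = tf
    return np.asarray(ref_t), np.asarray(ref_vl), np.asarray(ref_vd)


def evaluate_volumes(
    params: ModelParams,
    fraction_times: Sequence[float],
    times: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Viable and dying volumes at arbitrary times.

    Evaluation exactly at a fraction time returns the pre-fraction state.
    Times before ``t0`` follow the untreated pure-exponential backward
    extrapolation (no drug effect before treatment start).
    """
    fraction_times = np.asarray(fraction_times, dtype=float)
    times = np.asarray(times, dtype=float)
    _validate_fraction_times(params, fraction_times)
    if not np.all(np.isfinite(times)):
        raise ValueError("times must be finite")

    ref_t, ref_vl, ref_vd = _reference_states(params, fraction_times)
    lam = params.lambda_growth
    eps = params.epsilon

    v_live = np.empty_like(times)
    v_dead = np.empty_like(times)

    pre = times <= params.t0
    v_live[pre] = params.V0 * np.exp(lam * (times[pre] - params.t0))
    v_dead[pre] = 0.0

    post = ~pre
    if np.any(post):
        t_post = times[post]
        idx = np.searchsorted(ref_t, t_post, side="left") - 1
        idx = np.clip(idx, 0, len(ref_t) - 1)
        dt = t_post - ref_t[idx]
        gamma_ref = params.gamma0 * np.exp(-eps * (ref_t[idx] - params.t0))
        if eps < EPSILON_SWITCH:
            exponent = (lam - gamma_ref) * dt
        else:
            exponent = lam * dt + (gamma_ref / eps) * np.expm1(-eps * dt)
        v_live[post] = ref_vl[idx] * np.exp(exponent)
        v_dead[post] = ref_vd[idx] * np.exp(-lam * dt)
    return v_live, v_dead


@dataclass
class Trajectory:
    """Piecewise-analytic trajectory sampled at requested times plus the
    pre/post states at every fraction delivery.

    Rows with equal times are ordered (evaluation, pre-fraction,
    post-fraction) so the fraction discontinuity is explicit.  The
    originating parameters and fraction times are retained so downstream
    consumers can re-evaluate the closed form at arbitrary resolution.
    """

    params: ModelParams
    fraction_times: np.ndarray
    times: np.ndarray
    v_live: np.ndarray
    v_dead: np.ndarray
    is_fraction_pre: np.ndarray
    is_fraction_post: np.ndarray

    @property
    def v_total(self) -> np.ndarray:
        return self.v_live + self.v_dead

    def volume_at(self, times: Sequence[float]) -> np.ndarray:
        """Total observed volume at arbitrary times (pre-fraction at ties)."""
        vl, vd = evaluate_volumes(self.params, self.fraction_times, times)
        return vl + vd

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.times,
                "V_live_cm3": self.v_live,
                "V_dead_cm3": self.v_dead,
                "V_total_cm3": self.v_total,
                "is_fraction_pre": self.is_fraction_pre.astype(int),
                "is_fraction_post": self.is_fraction_post.astype(int),
            }
        )


def simulate_trajectory(
    params: ModelParams,
    fraction_times: Sequence[float],
    eval_times: Sequence[float],
) -> Trajectory:
    """Propagate the model through a fractionation schedule.

    Between fractions both compartments follow their closed forms; at each
    fraction time the same surviving fraction is applied.  The drug-kill
    rate decays on the global clock and is unaffected by fractions.
    """
    fraction_times = np.asarray(fraction_times, dtype=float)
    eval_times = np.asarray(eval_times, dtype=float)
    _validate_fraction_times(params, fraction_times)
    if eval_times.size and np.any(np.diff(eval_times) <= 0):
        raise ValueError("eval_times must be strictly increasing")
    if eval_times.size and eval_times[0] < params.t0:
        raise ValueError("eval_times must not precede t0")

    # rank breaks ties at fraction times: eval < pre < post
    rows: list[tuple[float, int, float, float, bool, bool]] = []

    vl_eval, vd_eval = evaluate_volumes(params, fraction_times, eval_times)
    for t, vl, vd in zip(eval_times, vl_eval, vd_eval):
        rows.append((t, 0, vl, vd, False, False))

    vl, vd, t_prev = params.V0, 0.0, params.t0
    for tf in fraction_times:
        gamma_ref = params.gamma_at(t_prev)
        vl = live_volume_analytic(vl, gamma_ref, params, t_prev, tf)
        vd = dead_volume_decay(vd, params.lambda_growth, tf - t_prev)
        rows.append((tf, 1, vl, vd, True, False))
        state = apply_fraction(TumorState(tf, vl, vd), params.surviving_fraction)
        vl, vd = state.V_live, state.V_dead
        rows.append((tf, 2, vl, vd, False, True))
        t_prev = tf

    rows.sort(key=lambda r: (r[0], r[1]))
    times = np.array([r[0] for r in rows])
    return Trajectory(
        params=params,
        fraction_times=fraction_times,
        times=times,
        v_live=np.array([r[2] for r in rows]),
        v_dead=np.array([r[3] for r in rows]),
        is_fraction_pre=np.array([r[4] for r in rows], dtype=bool),
        is_fraction_post=np.array([r[5] for r in rows], dtype=bool),
    )
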