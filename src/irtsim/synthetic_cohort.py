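"""Virtual-patient generator for end-to-end testing of the pipeline.

Draws patient-specific parameters (radiation surviving fraction uniform,
resistance-decay rate log-uniform by default, baseline volume uniform)
around a shared growth rate, simulates the ground-truth trajectory under
the trial's five daily fractions, samples it at jittered ~6-week
assessments, and applies the measurement noise model (20% multiplicative
noise, with an absolute 0.5 cm^3 floor below 2 cm^3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import Measurement
from .model_core import ModelParams, evaluate_volumes

__all__ = ["CohortSpec", "SyntheticPatient", "draw_patient", "draw_cohort", "child_seeds"]


@dataclass(frozen=True)
class CohortSpec:
    """Ranges and noise settings for virtual-patient generation."""

    n_patients: int = 16
    lambda_growth: float = 0.065
    s_range: tuple[float, float] = (0.07, 0.90)
    epsilon_range: tuple[float, float] = (0.05e-4, 202e-4)
    epsilon_log_uniform: bool = True
    v0_range: tuple[float, float] = (1.0, 60.0)
    n_post_range: tuple[int, int] = (4, 10)
    assessment_interval: float = 42.0
    interval_jitter_sd: float = 10.0
    min_interval: float = 7.0
    noise_rel_sd: float = 0.2
    small_volume_cut: float = 2.0
    small_volume_sd: float = 0.5
    geud_range: tuple[float, float] = (31.3, 37.5)
    treated: bool = True
    n_fractions: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("s_range", "epsilon_range", "v0_range", "geud_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be ordered")
        if not 0 <= self.s_range[0] <= self.s_range[1] <= 1:
            raise ValueError("s_range must lie within [0, 1]")
        if self.epsilon_range[0] < 0 or self.epsilon_range[1] > 0.1:
            raise ValueError("epsilon_range must lie within [0, 0.1]")
        if self.v0_range[0] <= 0:
            raise ValueError("v0_range must be positive")
        if not 4 <= self.n_post_range[0] <= self.n_post_range[1] <= 10:
            raise ValueError("n_post_range must lie within [4, 10]")


@dataclass
class SyntheticPatient:
    id: str
    true_params: ModelParams
    measurements: list[Measurement]
    cutoff_volume: float
    geud: float


def child_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Reproducible per-patient sub-seeds derived from the master seed."""
    return np.random.SeedSequence(master_seed).spawn(n)


def _draw_epsilon(spec: CohortSpec, rng: np.random.Generator) -> float:
    lo, hi = spec.epsilon_range
    if spec.epsilon_log_uniform:
        if lo <= 0:
            raise ValueError("log-uniform epsilon requires a positive lower bound")
        return float(10.0 ** rng.uniform(math.log10(lo), math.log10(hi)))
    return float(rng.uniform(lo, hi))


def _measurement_days(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Baseline at day 0 plus jittered ~6-week post-treatment days with a
    minimum spacing so ordering is preserved."""
    n_post = int(rng.integers(spec.n_post_range[0], spec.n_post_range[1] + 1))
    days = [0.0]
    for k in range(1, n_post + 1):
        nominal = k * spec.assessment_interval
        day = nominal + rng.normal(0.0, spec.interval_jitter_sd)
        day = max(day, days[-1] + spec.min_interval)
        days.append(day)
    return np.asarray(days)


def _apply_noise(true_volumes: np.ndarray, spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    noisy = np.empty_like(true_volumes)
    for i, v in enumerate(true_volumes):
        if v >= spec.small_volume_cut:
            noisy[i] = v * rng.normal(1.0, spec.noise_rel_sd)
        else:
            noisy[i] = v + rng.normal(0.0, spec.small_volume_sd)
    return np.maximum(noisy, 0.0)


def draw_patient(
    spec: CohortSpec,
    seed: int | np.random.SeedSequence,
    patient_id: str = "P00",
) -> SyntheticPatient:
    """Draw one virtual patient: parameters, ground-truth trajectory under
    the treated (or untreated) schedule, and noisy measurements."""
    rng = np.random.default_rng(seed)
    s = float(rng.uniform(*spec.s_range))
    eps = _draw_epsilon(spec, rng)
    v0 = float(rng.uniform(*spec.v0_range))
    params = ModelParams(
        lambda_growth=spec.lambda_growth,
        surviving_fraction=s,
        epsilon=eps,
        gamma0=spec.lambda_growth,
        V0=v0,
        t0=0.0,
    )
    fraction_times = (
        np.arange(spec.n_fractions, dtype=float) if spec.treated else np.array([])
    )
    days = _measurement_days(spec, rng)
    vl, vd = evaluate_volumes(params, fraction_times, days)
    true_volumes = vl + vd
    noisy = _apply_noise(true_volumes, spec, rng)
    measurements = [Measurement(day=float(d), volume=float(v)) for d, v in zip(days, noisy)]
    geud_value = float(rng.uniform(*spec.geud_range))
    return SyntheticPatient(
        id=patient_id,
        true_params=params,
        measurements=measurements,
        cutoff_volume=float(noisy[-1]),
        geud=geud_value,
    )


def draw_cohort(spec: CohortSpec) -> list[SyntheticPatient]:
    """Independent virtual patients with per-patient sub-seeds derived
    reproducibly from the master seed."""
    seeds = child_seeds(spec.seed, spec.n_patients)
    return [
        draw_patient(spec, seed, patient_id=f"P{i + 1:02d}")
        for i, seed in enumerate(seeds)
    ]
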