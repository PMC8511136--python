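"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's piecewise-analytic propagation:
the ODE system is integrated with an adaptive Runge-Kutta method, with
fraction deliveries applied as discrete events between integration
segments.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy.integrate import solve_ivp


def integrate_model(
    lambda_growth: float,
    surviving_fraction: float,
    epsilon: float,
    gamma0: float,
    V0: float,
    fraction_times: list[float],
    eval_times: np.ndarray,
    t0: float = 0.0,
    rtol: float = 1e-11,
    atol: float = 1e-13,
) -> np.ndarray:
    """Total volume at eval_times via brute-force numerical integration.

    Evaluation exactly at a fraction time returns the pre-fraction value.
    """

    def rhs(t, y):
        vl, vd = y
        gamma = gamma0 * np.exp(-epsilon * (t - t0))
        return [lambda_growth * vl - gamma * vl, -lambda_growth * vd]

    eval_times = np.asarray(eval_times, dtype=float)
    counts = Counter(float(t) for t in fraction_times)
    event_times = sorted(counts)
    horizon = max(
        float(eval_times.max(initial=t0)), event_times[-1] if event_times else t0
    )
    boundaries = event_times + ([horizon] if horizon > (event_times[-1] if event_times else t0) else [])

    out = np.empty_like(eval_times)
    filled = np.zeros(eval_times.shape, dtype=bool)

    pre = eval_times <= t0
    out[pre] = V0 * np.exp(lambda_growth * (eval_times[pre] - t0))
    filled[pre] = True

    y = np.array([V0, 0.0])
    t_prev = t0
    for seg_end in boundaries:
        if seg_end > t_prev:
            in_seg = (~filled) & (eval_times > t_prev) & (eval_times <= seg_end)
            ts = np.sort(eval_times[in_seg])
            t_eval = np.unique(np.append(ts, seg_end))
            sol = solve_ivp(
                rhs,
                (t_prev, seg_end),
                y,
                t_eval=t_eval,
                rtol=rtol,
                atol=atol,
                method="DOP853",
            )
            lookup = {t: i for i, t in enumerate(sol.t)}
            for idx in np.nonzero(in_seg)[0]:
                j = lookup[eval_times[idx]]
                out[idx] = sol.y[0, j] + sol.y[1, j]
                filled[idx] = True
            y = sol.y[:, -1].copy()
        for _ in range(counts.get(seg_end, 0)):
            killed = (1.0 - surviving_fraction) * y[0]
            y = np.array([surviving_fraction * y[0], y[1] + killed])
        t_prev = seg_end
    return out
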