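"""Independent fine-grid discretisation oracles for the event-loop tests.

These deliberately avoid the package's event-driven machinery: the
stable/relapse cycle is propagated on a fixed time grid as a cohort model
(relapse inflow at a constant hazard, deterministic return to stable after
the episode length), which gives expected event counts and state-occupancy
integrals to compare the DES engine against.
"""

import numpy as np


def stable_relapse_grid(rate: float, episode: float, horizon: float, dt: float = 1e-3):
    """Propagate P(stable) on a grid; returns (expected relapses,
    expected years stable, expected years in relapse)."""
    n = int(round(horizon / dt))
    lag = int(round(episode / dt))
    p_stable = 1.0
    inflow = np.zeros(n + lag + 1)
    relapses = 0.0
    years_stable = 0.0
    for k in range(n):
        r = rate * p_stable
        inflow[k] = r * dt
        relapses += r * dt
        years_stable += p_stable * dt
        p_stable += -r * dt + (inflow[k - lag] if k >= lag else 0.0)
    years_relapse = horizon - years_stable
    return relapses, years_stable, years_relapse


def markov_daily_qalys(
    rate: float, episode: float, horizon: float,
    u_stable: float, u_relapse: float, dt: float = 1.0 / 365.0,
):
    """Daily-cycle Markov cohort estimate of undiscounted QALYs for the
    two-state stable/relapse cycle (no death, no side-effects)."""
    _, ys, yr = stable_relapse_grid(rate, episode, horizon, dt)
    return u_stable * ys + u_relapse * yr
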