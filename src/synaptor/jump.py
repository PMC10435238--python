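"""Exact stochastic-jump sampling utilities.

Small exact samplers used by the test oracles and by low-dimensional parts of
the model: Gillespie simulation of a single particle on a constant-rate
Markov chain, and integrated-hazard (time-rescaling) sampling of jump times
for rates that vary in time — the statistically exact method for
piecewise-deterministic processes, where the cumulative hazard is integrated
along the deterministic flow and a jump fires when it crosses a unit-mean
exponential draw.
"""

from __future__ import annotations

from typing import Callable, Tuple

import numpy as np

__all__ = ["gillespie_path", "sample_hazard_crossing", "dwell_times"]


def gillespie_path(
    Q: np.ndarray,
    state0: int,
    n_jumps: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Exact path of a single particle on a constant generator ``Q``.

    Returns ``(jump_times, states)`` with ``states[0] = state0`` at time 0 and
    ``states[k]`` entered at ``jump_times[k]``.  Absorbing states terminate
    the path early.
    """
    n = Q.shape[0]
    rates = Q.copy()
    np.fill_diagonal(rates, 0.0)
    exit_rate = rates.sum(axis=1)
    times = [0.0]
    states = [state0]
    s = state0
    t = 0.0
    for _ in range(n_jumps):
        lam = exit_rate[s]
        if lam <= 0:
            break
        t += rng.exponential(1.0 / lam)
        s = rng.choice(n, p=rates[s] / lam)
        times.append(t)
        states.append(s)
    return np.asarray(times), np.asarray(states)


def dwell_times(times: np.ndarray, states: np.ndarray, state: int) -> np.ndarray:
    """Sojourn durations spent in ``state`` along a jump path."""
    idx = np.nonzero(states[:-1] == state)[0]
    return times[idx + 1] - times[idx]


def sample_hazard_crossing(
    rate_fn: Callable[[float], float],
    t0: float,
    t_max: float,
    rng: np.random.Generator,
    dt: float = 1e-4,
) -> float:
    """Sample the next jump time for a time-varying rate on [t0, t_max].

    The cumulative hazard Λ(t) = ∫ rate(s) ds is accumulated with the
    trapezoidal rule on steps of ``dt`` until it crosses an Exp(1) draw; the
    crossing is located by linear interpolation within the step (refined by
    bisection on the interpolated hazard).  Returns ``inf`` if no jump occurs
    before ``t_max``.
    """
    target = rng.exponential(1.0)
    t = t0
    lam_prev = rate_fn(t)
    acc = 0.0
    while t < t_max:
        h = min(dt, t_max - t)
        lam_next = rate_fn(t + h)
        inc = 0.5 * (lam_prev + lam_next) * h
        if acc + inc >= target:
            # linear-in-t hazard within the step: solve the quadratic exactly
            a = 0.5 * (lam_next - lam_prev) / h
            b = lam_prev
            c = acc - target
            if abs(a) < 1e-15:
                dt_star = -c / b if b > 0 else h
            else:
                disc = b * b - 4 * a * c
                dt_star = (-b + np.sqrt(max(disc, 0.0))) / (2 * a)
            return t + min(max(dt_star, 0.0), h)
        acc += inc
        lam_prev = lam_next
        t += h
    return np.inf
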