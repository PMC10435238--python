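"""Stochastic presynaptic terminal: vesicle pools, release probability,
transmitter pulses.

Vesicles occupy a docked pool (D, fast releasing) replenished from a reserve
pool (R); both are integer-valued birth-death processes whose rates vanish at
the pool bounds, simulated exactly (Gillespie) between spikes.  Each
presynaptic spike updates a phenomenological calcium resource (jump + decay
with use-dependent jump depression) and then releases one vesicle with
probability ``p_rel(Ca_pre, [Ca²⁺]o, D)`` — a Hill sigmoid in the calcium
resource whose threshold falls with extracellular calcium.  A successful
release ejects a glutamate pulse with gamma-distributed amplitude (mean
1000 µM, 1 ms); the same pulse amplitude and timing is copied to the
co-released GABA signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .conditions import ExperimentalConditions
from .params import ParameterSet, default_params

__all__ = [
    "pool_propensities", "release_threshold", "release_probability",
    "PresynapticTrace", "simulate_presynapse",
]


def pool_propensities(docked: int, reserve: int,
                      params: ParameterSet | None = None):
    """(refill, mixing, replenish) rates, s⁻¹, for pool state (D, R).

    refill:     (R, D) -> (R-1, D+1) at (D0-D)·R/τ_D
    mixing:     (R, D) -> (R+1, D-1) at (R0-R)·D/τ_R
    replenish:  (R, D) -> (R+1, D)   at (R0-R)/τ_R_ref
    """
    p = params or default_params()
    if not (0 <= docked <= p["D0"] and 0 <= reserve <= p["R0"]):
        raise ValueError("pool state outside bounds")
    refill = (p["D0"] - docked) * reserve / p["tau_D"]
    mixing = (p["R0"] - reserve) * docked / p["tau_R"]
    replenish = (p["R0"] - reserve) / p["tau_R_ref"]
    return refill, mixing, replenish


def release_threshold(ca_o: float, params: ParameterSet | None = None) -> float:
    """Half-activation h([Ca²⁺]o) of the release sigmoid (decreasing in Ca)."""
    if ca_o <= 0:
        raise ValueError("ca_o must be positive")
    p = params or default_params()
    z = min(p["h_rel_slope"] * (ca_o - p["h_rel_mid"]), 700.0)
    return p["h_rel_base"] + p["h_rel_amp"] / (1.0 + math.exp(z))


def release_probability(ca_pre: float, ca_o: float, docked: int,
                        params: ParameterSet | None = None) -> float:
    """p_rel = Ca_pre² / (Ca_pre² + h²) if any vesicle is docked, else 0."""
    if docked <= 0:
        return 0.0
    p = params or default_params()
    h = release_threshold(ca_o, p)
    c = ca_pre ** p["s_rel"]
    return c / (c + h ** p["s_rel"])


@dataclass
class PresynapticTrace:
    """Per-spike presynaptic record for one sample run.

    All arrays are aligned with ``times`` (one entry per presynaptic spike).
    """

    times: np.ndarray        # spike times, s
    ca_pre: np.ndarray       # calcium resource just after the spike jump
    p_rel: np.ndarray        # release probability used for the draw
    released: np.ndarray     # bool, vesicle released
    glu_amp: np.ndarray      # µM, transmitter pulse amplitude (0 on failure)
    docked: np.ndarray       # D just before the release decision
    reserve: np.ndarray      # R just before the release decision

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "time": self.times, "ca_pre": self.ca_pre, "p_rel": self.p_rel,
            "released": self.released, "glu_amp": self.glu_amp,
            "docked": self.docked, "reserve": self.reserve,
        })


def _gillespie_pools(D: int, R: int, t0: float, t1: float,
                     p: ParameterSet, rng: np.random.Generator):
    """Exact simulation of the pool birth-death process over [t0, t1]."""
    t = t0
    while True:
        a1, a2, a3 = pool_propensities(D, R, p)
        total = a1 + a2 + a3
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t >= t1:
            break
        u = rng.random() * total
        if u < a1:
            D += 1; R -= 1
        elif u < a1 + a2:
            D -= 1; R += 1
        else:
            R += 1
    return D, R


def _integrate_ca_jump(ca_pre0: float, jump0: float, dt: float,
                       p: ParameterSet, n_sub: int = 32):
    """Advance (Ca_pre, Ca_jump) over a spike-free interval of length dt.

    Ca_pre decays in closed form; the jump-size recovery ODE (linear with the
    exponentially decaying Ca_pre as coefficient) is integrated with RK4.
    """
    tau_p, tau_r, dca = p["tau_pre"], p["tau_rec_pre"], p["delta_ca_pre"]
    if dt <= 0:
        return ca_pre0, jump0
    # cap the substep at ~tau_pre/8 while Ca_pre is non-negligible
    n = max(n_sub, int(dt / (tau_p / 8)) + 1) if ca_pre0 > 1e-12 else 8
    n = min(n, 4096)
    h = dt / n
    J = jump0

    def f(tt, JJ):
        c = ca_pre0 * math.exp(-tt / tau_p)
        return (1.0 - JJ) / tau_r - dca * JJ * c

    t = 0.0
    for _ in range(n):
        k1 = f(t, J)
        k2 = f(t + h / 2, J + h * k1 / 2)
        k3 = f(t + h / 2, J + h * k2 / 2)
        k4 = f(t + h, J + h * k3)
        J += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return ca_pre0 * math.exp(-dt / tau_p), J


def simulate_presynapse(
    pre_times: np.ndarray,
    conditions: ExperimentalConditions | None = None,
    rng: np.random.Generator | None = None,
) -> PresynapticTrace:
    """Simulate the presynaptic terminal over one protocol sample.

    Returns the per-spike trace (release decisions, pool occupancies,
    transmitter amplitudes).  Release draws depend only on presynaptic state,
    never on the postsynaptic simulation, so this runs ahead of it.

    ``conditions.forced_release`` makes every spike release (uncaging mode);
    ``"presyn" in conditions.deterministic_sources`` switches the pools to
    their mean-field ODE and replaces the Bernoulli release by a pulse of
    expected amplitude ``p_rel × amplitude``.
    """
    cond = conditions or ExperimentalConditions()
    p = cond.params
    rng = rng or np.random.default_rng()
    pre = np.asarray(pre_times, dtype=float)
    n = pre.size
    deterministic = cond.is_deterministic("presyn")

    D, R = float(p["D0"]), float(p["R0"])
    ca_pre, jump = 0.0, 1.0
    t_prev = 0.0

    out = dict(
        times=pre, ca_pre=np.zeros(n), p_rel=np.zeros(n),
        released=np.zeros(n, dtype=bool), glu_amp=np.zeros(n),
        docked=np.zeros(n), reserve=np.zeros(n),
    )
    gamma_shape = 1.0 / p["glu_cv"]
    gamma_scale = p["glu_cv"]

    for i, t in enumerate(pre):
        dt = t - t_prev
        if deterministic:
            D, R = _mean_field_pools(D, R, dt, p)
        else:
            D, R = _gillespie_pools(int(D), int(R), t_prev, t, p, rng)
        ca_pre, jump = _integrate_ca_jump(ca_pre, jump, dt, p)
        # spike: calcium resource jump, then the release decision
        ca_pre += jump
        prob = release_probability(ca_pre, cond.ca_o, int(round(D)), p)
        out["ca_pre"][i] = ca_pre
        out["p_rel"][i] = prob
        out["docked"][i] = D
        out["reserve"][i] = R
        if deterministic:
            out["released"][i] = prob > 0
            out["glu_amp"][i] = p["glu_amp"] * prob
            D = max(D - prob, 0.0)
        else:
            hit = cond.forced_release or (rng.random() < prob)
            if hit:
                out["released"][i] = True
                out["glu_amp"][i] = p["glu_amp"] * rng.gamma(gamma_shape,
                                                             gamma_scale)
                if D >= 1:
                    D -= 1
        t_prev = t

    return PresynapticTrace(**out)


def _mean_field_pools(D: float, R: float, dt: float, p: ParameterSet,
                      max_h: float = 0.05):
    """RK4 mean-field pool dynamics over a spike-free interval."""
    if dt <= 0:
        return D, R

    def f(y):
        d, r = y
        refill = (p["D0"] - d) * r / p["tau_D"]
        mixing = (p["R0"] - r) * d / p["tau_R"]
        repl = (p["R0"] - r) / p["tau_R_ref"]
        return np.array([refill - mixing, -refill + mixing + repl])

    n = max(1, int(dt / max_h))
    h = dt / n
    y = np.array([D, R], dtype=float)
    for _ in range(n):
        k1 = f(y); k2 = f(y + h / 2 * k1)
        k3 = f(y + h / 2 * k2); k4 = f(y + h * k3)
        y += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return float(np.clip(y[0], 0, p["D0"])), float(np.clip(y[1], 0, p["R0"]))
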