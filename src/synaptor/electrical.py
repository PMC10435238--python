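"""Three-compartment electrical model and action-potential back-propagation.

A spherical spine is coupled through its neck to a single passive dendrite,
itself coupled to a spherical soma that generates action potentials with
Hodgkin-Huxley-style Na⁺/K⁺ currents.  Postsynaptic spikes are produced by
rectangular current injections into the soma; the resulting BaP reaches the
dendrite and spine attenuated by the distance factor and by a use-dependent
resource variable (λ), with an additional age-dependent resource (λ_age)
scaling the somatic spike currents.

The attenuation resources follow resource-use dynamics: each somatic
injection consumes a step of λ (amplified as the auxiliary resource λ_aux
depletes) and λ recovers exponentially between spikes.  The published step
constants are coupled to the injected current through a unit convention that
does not survive in print; the product (step constant × injection drive) is
the physically meaningful per-spike use and is represented here by the
calibrated ``bap_use_scale`` drive (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .conditions import ExperimentalConditions, bap_age_step, phi_dist
from .params import ParameterSet, default_params

__all__ = [
    "soma_gate_rates", "soma_gate_steady",
    "sodium_current", "potassium_current",
    "g_bap_adapt", "bap_injection",
    "adaptation_derivatives", "evoked_ap_times",
    "ElectricalTrace", "simulate_electrical",
]


def _x_over_expm1(x, k):
    """x / (exp(x/k) - 1) with the removable singularity at x = 0."""
    x = np.asarray(x, dtype=float)
    r = np.empty_like(x)
    small = np.abs(x) < 1e-4 * k
    xs = x[small]
    # 2nd-order series: k * (1 - x/(2k) + x^2/(12 k^2))
    r[small] = k * (1.0 - xs / (2 * k) + xs * xs / (12 * k * k))
    xb = x[~small]
    r[~small] = xb / np.expm1(xb / k)
    return r


def soma_gate_rates(v_soma):
    """Somatic spike-gate rates, s⁻¹ (the literature prints them in ms⁻¹).

    Returns ``(alpha_m, beta_m, alpha_h, beta_h, n_inf, n_tau)`` with
    ``n_tau`` in seconds; the K⁺ activation is specified through its steady
    state and a floored time constant rather than raw rates.
    """
    v = np.asarray(v_soma, dtype=float)
    am = 0.4 * _x_over_expm1(-(v + 30.0), 7.2)          # = 0.4(v+30)/(1-e^{-(v+30)/7.2})
    bm = 0.124 * _x_over_expm1(v + 30.0, 7.2)
    ah = 0.01 * _x_over_expm1(v + 45.0, 1.5)
    bh = 0.03 * _x_over_expm1(-(v + 45.0), 1.5)
    an = np.exp(-0.11 * (v - 13.0))
    bn = np.exp(-0.08 * (v - 13.0))
    n_inf = 1.0 / (1.0 + an)
    n_tau = np.maximum(50.0 * bn / (1.0 + an), 2.0)     # ms, floored at 2 ms
    return am * 1e3, bm * 1e3, ah * 1e3, bh * 1e3, n_inf, n_tau * 1e-3


def soma_gate_steady(v_soma):
    """Steady-state (m, h, n) at a holding potential."""
    am, bm, ah, bh, n_inf, _ = soma_gate_rates(v_soma)
    return am / (am + bm), ah / (ah + bh), n_inf


def sodium_current(v_soma, m, h, params: ParameterSet | None = None):
    p = params or default_params()
    return p["gamma_Na"] * m ** 3 * h * (p["Erev_Na"] - v_soma)


def potassium_current(v_soma, n, params: ParameterSet | None = None):
    p = params or default_params()
    return p["gamma_K"] * n * (p["Erev_K"] - v_soma)


def g_bap_adapt(lambda_, d_soma, params: ParameterSet | None = None):
    """Soma-dendrite axial conductance (nS): λ · g_diff · φ_dist(d)."""
    p = params or default_params()
    return lambda_ * p["g_diff"] * phi_dist(d_soma)


def bap_injection(t, post_times: np.ndarray, i_amp: float, delta_inj: float):
    """Somatic injection current (pA) at time ``t``: rectangular pulses of
    width ``delta_inj`` at each postsynaptic spike time; overlaps sum."""
    post = np.asarray(post_times)
    if post.size == 0:
        return 0.0
    inside = (t >= post) & (t < post + delta_inj)
    return i_amp * int(np.count_nonzero(inside))


def adaptation_derivatives(lam, lam_aux, lam_age, use_drive,
                           conditions: ExperimentalConditions):
    """Resource-use derivatives (dλ/dt, dλ_aux/dt, dλ_age/dt).

    ``use_drive`` is the calibrated injection drive (``bap_use_scale`` during
    an injection pulse, 0 otherwise)."""
    p = conditions.params
    d_age = bap_age_step(conditions.age)
    dlam = (1.0 - lam) / p["tau_rec_bap"] - p["delta_decay"] / np.maximum(
        lam_aux, 1e-6) * lam * use_drive
    daux = (1.0 - lam_aux) / p["tau_rec_bap"] - p["delta_aux"] * lam_aux * use_drive
    dage = (1.0 - lam_age) / p["tau_rec_age"] - d_age * lam_age * use_drive
    return dlam, daux, dage


def evoked_ap_times(
    pre_times: np.ndarray,
    docked_at_spike: np.ndarray,
    conditions: ExperimentalConditions,
    rng: np.random.Generator,
) -> np.ndarray:
    """Postsynaptic AP times evoked by EPSPs (field-stimulation mode).

    An EPSP-summation proxy is incremented by 1 at each presynaptic spike and
    decays with τ_V; at each spike, 25 afferent synapses are tested with the
    release-probability function evaluated at the proxy value, and an AP is
    evoked (with a 15 ms latency) when more than 80% of them succeed.
    Decisions are drawn before the main simulation from a dedicated stream.
    """
    from .presynapse import release_probability

    p = conditions.params
    v_evoke = 0.0
    t_prev = None
    out = []
    for t, docked in zip(pre_times, docked_at_spike):
        if t_prev is not None:
            v_evoke *= math.exp(-(t - t_prev) / p["tau_V_evoke"])
        v_evoke += 1.0
        t_prev = t
        prob = release_probability(v_evoke, conditions.ca_o, int(docked),
                                   params=p)
        n_ok = int(rng.binomial(p["n_syn_evoke"], prob))
        if n_ok / p["n_syn_evoke"] > p["evoke_threshold"]:
            out.append(t + p["delta_delay_AP"])
    return np.asarray(out)


# ----------------------------------------------------------------------
# deterministic electrical-only simulation (no synaptic conductances)
# ----------------------------------------------------------------------

@dataclass
class ElectricalTrace:
    t: np.ndarray
    v_sp: np.ndarray
    v_dend: np.ndarray
    v_soma: np.ndarray
    lam: np.ndarray
    lam_age: np.ndarray

    def pulse_peaks(self, post_times: Sequence[float], which: str = "v_dend",
                    window: float = 0.03) -> np.ndarray:
        """Peak depolarisation above rest after each postsynaptic time."""
        v = getattr(self, which)
        rest = v[0]
        peaks = []
        for tp in post_times:
            m = (self.t >= tp) & (self.t <= tp + window)
            peaks.append(v[m].max() - rest if m.any() else np.nan)
        return np.asarray(peaks)


def simulate_electrical(
    post_times: Sequence[float],
    conditions: ExperimentalConditions | None = None,
    t_end: float | None = None,
    dt_out: float = 1e-4,
) -> ElectricalTrace:
    """Integrate the three-compartment model with somatic injections only.

    This is the deterministic electrical subsystem: no synaptic channels, no
    calcium — it isolates BaP generation, propagation and use-dependent
    attenuation (the protocol's postsynaptic side).
    """
    cond = conditions or ExperimentalConditions()
    p = cond.params
    post = np.sort(np.asarray(post_times, dtype=float))
    if t_end is None:
        t_end = (post[-1] if post.size else 0.0) + 0.1

    EL = p["E_leak"]
    m0, h0, n0 = soma_gate_steady(EL)
    y0 = np.array([EL, EL, EL, m0, h0, n0, 1.0, 1.0, 1.0])

    def rhs(t, y, inj):
        vsp, vd, vs, m, h, n, lam, laux, lage = y
        am, bm, ah, bh, n_inf, n_tau = soma_gate_rates(vs)
        g_ad = g_bap_adapt(lam, cond.d_soma, p)
        i_na = sodium_current(vs, m, h, p)
        i_k = potassium_current(vs, n, p)
        dvsp = (p["g_neck"] * (vd - vsp) + p["gL_sp"] * (EL - vsp)) / p["C_sp"] * 1e3
        dvd = (g_ad * (vs - vd) + p["g_neck"] * (vsp - vd)
               + p["gL_dend"] * (EL - vd)) / p["C_dend"] * 1e3
        dvs = (g_ad * (vd - vs) + p["gL_soma"] * (EL - vs)
               + lage * (inj + i_na) + i_k) / p["C_soma"] * 1e3
        dm = am * (1 - m) - bm * m
        dh = ah * (1 - h) - bh * h
        dn = (n_inf - n) / n_tau
        use = p["bap_use_scale"] if inj > 0 else 0.0
        dlam, daux, dage = adaptation_derivatives(lam, laux, lage, use, cond)
        return [dvsp, dvd, dvs, dm, dh, dn, dlam, daux, dage]

    # integrate piecewise between injection edges so pulses are sharp
    edges = np.unique(np.concatenate(
        [[0.0, t_end], post, post + p["delta_inj"]]))
    edges = edges[(edges >= 0.0) & (edges <= t_end)]
    ts, ys = [np.array([0.0])], [y0[:, None]]
    y = y0
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a < 1e-12:
            continue
        mid = 0.5 * (a + b)
        inj = bap_injection(mid, post, p["I_amp"], p["delta_inj"])
        t_eval = np.arange(a, b, dt_out)[1:]
        t_eval = t_eval[(t_eval > a) & (t_eval < b)]
        sol = solve_ivp(rhs, (a, b), y, args=(inj,), method="LSODA",
                        t_eval=np.append(t_eval, b), rtol=1e-7, atol=1e-8,
                        max_step=(b - a) if inj == 0 else 1e-4)
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"electrical integration failed: {sol.message}")
        ts.append(sol.t)
        ys.append(sol.y)
        y = sol.y[:, -1]
    t = np.concatenate(ts)
    Y = np.concatenate(ys, axis=1)
    return ElectricalTrace(t, Y[0], Y[1], Y[2], Y[6], Y[8])
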