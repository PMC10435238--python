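"""Markov-chain schemes and currents for the postsynaptic channel populations.

Four stochastic channel classes are modelled as finite continuous-time Markov
chains whose transition rates depend on the ligand concentration (AMPAr,
NMDAr, GABA(A)r) or the spine voltage (VGCC), plus a deterministic SK channel:

* AMPAr — 16 states: closed C0–C4, open O2–O4 (three subconductances),
  desensitised D0–D4 and deep-desensitised D22–D24.
* NMDAr — two subtypes (GluN2A / GluN2B) each a 7-state linear chain
  A0–A4, AO1, AO2 with the two final states conducting; the GluN2B chain
  uses the GluN2A rates scaled by fixed fractions (0.25 forward /
  0.23 backward), which is what makes it ~5× slower.
* GABA(A)r — 5 states C0–C2, O1, O2 (ligand-gated chloride channel).
* VGCC — T- and R-type channels factor into independent activation (m) and
  inactivation (h) two-state gates; the L-type is a 3-state chain
  {C, O1, O2} with two closing timescales.

Rate matrices are returned as generators ``Q`` with ``Q[i, j]`` the i→j rate
(s⁻¹) and ``Q[i, i] = -sum_j Q[i, j]``; ligand binding rates are in
µM⁻¹ s⁻¹ × [ligand in µM].  Temperature enters through the per-mechanism
logistic factors of :mod:`synaptor.conditions`; the placement of those factors
(which transitions they scale) follows the fitted kinetics for each class.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np
from scipy.linalg import expm

from .conditions import temperature_factors
from .params import ParameterSet, default_params

__all__ = [
    "AMPA_STATES", "NMDA_STATES", "GABA_STATES",
    "ampar_Q", "nmdar_Q", "gabar_Q",
    "AMPA_OPEN", "NMDA_OPEN", "GABA_OPEN",
    "ampar_conductance", "ampar_current",
    "mg_block", "gabar_current",
    "vgcc_gate_rates", "vgcc_l_rates",
    "sk_activation", "sk_derivative", "sk_current",
    "stationary_distribution", "occupancy_decay_tau",
]

# ----------------------------------------------------------------------
# AMPAr
# ----------------------------------------------------------------------

AMPA_STATES = (
    "C0", "C1", "C2", "C3", "C4",
    "O2", "O3", "O4",
    "D0", "D1", "D2", "D3", "D4",
    "D22", "D23", "D24",
)
_A = {s: i for i, s in enumerate(AMPA_STATES)}
#: indices of the conducting states (three subconductance levels)
AMPA_OPEN = (_A["O2"], _A["O3"], _A["O4"])


def ampar_Q(glu: float, T: float, params: ParameterSet | None = None) -> np.ndarray:
    """AMPAr generator matrix for cleft glutamate ``glu`` (µM) at ``T`` °C.

    Temperature scales the glutamate binding (forward factor) and unbinding
    (backward factor) steps only; the gating (open/close) and desensitisation
    transitions keep their room-temperature values, consistent with the
    observation that recovery from desensitisation is temperature-insensitive.
    """
    if glu < 0:
        raise ValueError("glutamate concentration must be non-negative")
    p = params or default_params()
    rho = temperature_factors(T, "AMPA")
    k1 = p["ampa_k1"] * rho.rho_f * glu
    k_1 = p["ampa_k_1"] * rho.rho_b
    k_2 = p["ampa_k_2"] * rho.rho_b
    al, be = p["ampa_alpha"], p["ampa_beta"]
    d0, d1, d2 = p["ampa_delta_0"], p["ampa_delta_1"], p["ampa_delta_2"]
    g0, g1, g2 = p["ampa_gamma_0"], p["ampa_gamma_1"], p["ampa_gamma_2"]

    Q = np.zeros((16, 16))

    def put(a, b, rate):
        Q[_A[a], _A[b]] = rate

    # closed-row glutamate binding / unbinding (statistical multiplicities)
    put("C0", "C1", 4 * k1); put("C1", "C0", 1 * k_1)
    put("C1", "C2", 3 * k1); put("C2", "C1", 2 * k_1)
    put("C2", "C3", 2 * k1); put("C3", "C2", 3 * k_1)
    put("C3", "C4", 1 * k1); put("C4", "C3", 4 * k_1)
    # opening / closing from the doubly-to-fully liganded closed states
    put("C2", "O2", be); put("O2", "C2", al)
    put("C3", "O3", be); put("O3", "C3", al)
    put("C4", "O4", be); put("O4", "C4", al)
    # desensitisation (vertical transitions, temperature-insensitive)
    put("C0", "D0", d0); put("D0", "C0", g0)
    put("C1", "D1", d1); put("D1", "C1", g1)
    put("C2", "D2", d2); put("D2", "C2", g2)
    put("C3", "D3", d2); put("D3", "C3", g2)
    put("C4", "D4", d2); put("D4", "C4", g2)
    # desensitised-row glutamate binding (same k1) / slow unbinding (k_2)
    put("D0", "D1", 4 * k1); put("D1", "D0", 1 * k_2)
    put("D1", "D2", 3 * k1); put("D2", "D1", 2 * k_2)
    put("D2", "D3", 2 * k1); put("D3", "D2", 3 * k_2)
    put("D3", "D4", 1 * k1); put("D4", "D3", 4 * k_2)
    # deep desensitisation below the liganded desensitised states
    put("D2", "D22", d2); put("D22", "D2", g2)
    put("D3", "D23", d2); put("D23", "D3", g2)
    put("D4", "D24", d2); put("D24", "D4", g2)

    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def ampar_conductance(counts: np.ndarray, params: ParameterSet | None = None):
    """Total AMPAr conductance (nS) from state counts (last axis = 16 states)."""
    p = params or default_params()
    counts = np.asarray(counts)
    return (
        p["gamma_A2"] * counts[..., _A["O2"]]
        + p["gamma_A3"] * counts[..., _A["O3"]]
        + p["gamma_A4"] * counts[..., _A["O4"]]
    )


def ampar_current(counts: np.ndarray, v_sp, params: ParameterSet | None = None):
    """AMPAr current (pA), positive = depolarising, reversal at 0 mV."""
    p = params or default_params()
    return ampar_conductance(counts, p) * (p["Erev_AMPA"] - v_sp)


# ----------------------------------------------------------------------
# NMDAr
# ----------------------------------------------------------------------

NMDA_STATES = ("A0", "A1", "A2", "A3", "A4", "AO1", "AO2")
#: indices of the conducting states
NMDA_OPEN = (5, 6)


def nmdar_Q(
    glu: float,
    T: float,
    subtype: str = "GluN2A",
    params: ParameterSet | None = None,
) -> np.ndarray:
    """NMDAr generator matrix for one subtype at ``T`` °C.

    The chain is linear: two glutamate-binding steps, three conformational
    steps, and a final open-open step; forward rates carry the forward
    temperature factor and backward rates the backward factor.
    """
    if glu < 0:
        raise ValueError("glutamate concentration must be non-negative")
    p = params or default_params()
    rho = temperature_factors(T, "NMDA")
    fwd = np.array([
        p["nmda_ka"] * glu, p["nmda_kb"] * glu,
        p["nmda_kc"], p["nmda_kd"], p["nmda_ke"], p["nmda_kf"],
    ])
    bwd = np.array([
        p["nmda_k_a"], p["nmda_k_b"], p["nmda_k_c"],
        p["nmda_k_d"], p["nmda_k_e"], p["nmda_k_f"],
    ])
    st = subtype.upper()
    if st == "GLUN2B":
        fwd = fwd * p["glun2b_fwd_frac"]
        bwd = bwd * p["glun2b_bwd_frac"]
    elif st != "GLUN2A":
        raise ValueError(f"unknown NMDAr subtype {subtype!r}")
    fwd = fwd * rho.rho_f
    bwd = bwd * rho.rho_b

    Q = np.zeros((7, 7))
    for i in range(6):
        Q[i, i + 1] = fwd[i]
        Q[i + 1, i] = bwd[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def mg_block(v_sp, mg_o: float, params: ParameterSet | None = None):
    """Fraction of NMDAr conductance surviving the voltage-dependent Mg block."""
    if np.any(np.asarray(mg_o) < 0):
        raise ValueError("mg_o must be non-negative")
    p = params or default_params()
    return 1.0 / (1.0 + (mg_o / p["mg_K0"]) * np.exp(-p["mg_slope"] * np.asarray(v_sp)))


# ----------------------------------------------------------------------
# GABA(A)r
# ----------------------------------------------------------------------

GABA_STATES = ("C0", "C1", "C2", "O1", "O2")
#: indices of the conducting states
GABA_OPEN = (3, 4)


def gabar_Q(gaba: float, T: float, params: ParameterSet | None = None) -> np.ndarray:
    """GABA(A)r generator matrix; temperature scales only the closing rates."""
    if gaba < 0:
        raise ValueError("GABA concentration must be non-negative")
    p = params or default_params()
    rho_b = temperature_factors(T, "GABA").rho_b
    Q = np.zeros((5, 5))
    Q[0, 1] = p["gaba_rb1"] * gaba
    Q[1, 0] = p["gaba_ru1"]
    Q[1, 2] = p["gaba_rb2"] * gaba
    Q[2, 1] = p["gaba_ru2"]
    Q[1, 3] = p["gaba_ro1"]
    Q[3, 1] = p["gaba_rc1"] * rho_b
    Q[2, 4] = p["gaba_ro2"]
    Q[4, 2] = p["gaba_rc2"] * rho_b
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def gabar_current(counts: np.ndarray, v_dend, erev_cl: float,
                  params: ParameterSet | None = None):
    """GABA(A)r dendritic current (pA); sign set by Erev(Cl) vs Vdend."""
    p = params or default_params()
    counts = np.asarray(counts)
    n_open = counts[..., GABA_OPEN[0]] + counts[..., GABA_OPEN[1]]
    return n_open * p["gamma_GABA"] * (erev_cl - v_dend)


# ----------------------------------------------------------------------
# VGCC
# ----------------------------------------------------------------------

def _t_type_minf(v):
    return 1.0 / (1.0 + np.exp((-32.0 - np.asarray(v)) / 7.0))


def _t_type_hinf(v):
    return 1.0 / (1.0 + np.exp((np.asarray(v) + 70.0) / 6.5))


def _r_type_minf(v):
    return 1.0 / (1.0 + np.exp((3.0 - np.asarray(v)) / 8.0))


def _r_type_hinf(v):
    return 1.0 / (1.0 + np.exp((np.asarray(v) + 39.0) / 9.2))


# gate reference constants (ms⁻¹ / ms), converted to s⁻¹ at evaluation
_BETA_M_T_STAR = 1.0    # ms⁻¹
_MINF_T_STAR = 1.0 / (1.0 + math.exp((-32.0 + 20.0) / 7.0))
_TAU_M_T = 1.0 / (_BETA_M_T_STAR * _MINF_T_STAR / (1 - _MINF_T_STAR) + _BETA_M_T_STAR)
_TAU_H_T = 50.0         # ms
_BETA_M_R_STAR = 40.0   # ms⁻¹
_MINF_R_STAR = 1.0 / (1.0 + math.exp((3.0 - 10.0) / 8.0))
_TAU_M_R = 1.0 / (_BETA_M_R_STAR * _MINF_R_STAR / (1 - _MINF_R_STAR) + _BETA_M_R_STAR)
_TAU_H_R = 100.0        # ms


def vgcc_gate_rates(v_sp, T: float, subtype: str, gate: str):
    """(alpha, beta) rates in s⁻¹ for a T- or R-type activation (m) or
    inactivation (h) two-state gate, temperature-scaled (forward factor on
    alpha, backward factor on beta)."""
    rho = temperature_factors(T, "VGCC")
    st, g = subtype.upper(), gate.lower()
    if st == "T":
        if g == "m":
            inf, tau = _t_type_minf(v_sp), _TAU_M_T
        elif g == "h":
            inf, tau = _t_type_hinf(v_sp), _TAU_H_T
        else:
            raise ValueError(f"unknown gate {gate!r}")
    elif st == "R":
        if g == "m":
            inf, tau = _r_type_minf(v_sp), _TAU_M_R
        elif g == "h":
            inf, tau = _r_type_hinf(v_sp), _TAU_H_R
        else:
            raise ValueError(f"unknown gate {gate!r}")
    else:
        raise ValueError(f"unknown VGCC subtype {subtype!r}")
    alpha = inf / tau * 1e3 * rho.rho_f          # s⁻¹
    beta = (1.0 - inf) / tau * 1e3 * rho.rho_b   # s⁻¹
    return alpha, beta


def vgcc_l_rates(v_sp, T: float):
    """L-type rates (s⁻¹): (alpha, beta1, beta2) for C->O1/O2, O1->C, O2->C."""
    rho = temperature_factors(T, "VGCC")
    v = np.asarray(v_sp)
    alpha = 0.83 / (1.0 + np.exp((13.7 - v) / 6.1)) * 1e3 * rho.rho_f
    beta1 = 0.53 / (1.0 + np.exp((v - 11.5) / 6.4)) * 1e3 * rho.rho_b
    beta2 = 1.86 / (1.0 + np.exp((v - 18.8) / 6.17)) * 1e3 * rho.rho_b
    return alpha, beta1, beta2


# ----------------------------------------------------------------------
# SK channel (deterministic)
# ----------------------------------------------------------------------

def sk_activation(ca, params: ParameterSet | None = None):
    """Calcium activation sigmoid r(Ca) of the SK channel (Hill form)."""
    p = params or default_params()
    ca = np.maximum(np.asarray(ca, dtype=float), 0.0)
    cas = ca ** p["sigma_SK"]
    return cas / (cas + p["h_SK"] ** p["sigma_SK"])


def sk_derivative(m_sk, ca, T: float, params: ParameterSet | None = None):
    """dm/dt of the SK activation variable (temperature-scaled kinetics)."""
    p = params or default_params()
    rho = temperature_factors(T, "SK")
    return sk_activation(ca, p) * rho.rho_f - m_sk / (p["tau_SK"] * rho.rho_b)


def sk_current(m_sk, v_sp, params: ParameterSet | None = None):
    """SK channel current (pA); hyperpolarising for Vsp above -90 mV."""
    p = params or default_params()
    return p["gamma_SK"] * p["N_SK"] * np.asarray(m_sk) * (p["Erev_SK"] - v_sp)


# ----------------------------------------------------------------------
# generic chain utilities
# ----------------------------------------------------------------------

def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a generator matrix (null-space solve)."""
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def occupancy_decay_tau(
    Q_pulse: np.ndarray,
    Q_rest: np.ndarray,
    open_idx: Tuple[int, ...],
    pulse_width: float = 1e-3,
    horizon: float = 0.5,
    dt: float = 1e-5,
    start_state: int = 0,
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Deterministic open-probability decay constant after a ligand pulse.

    Propagates the occupancy distribution through a square ligand pulse
    (generator ``Q_pulse`` for ``pulse_width`` seconds) and then relaxation
    (``Q_rest``), and fits a single exponential ``a*exp(-t/tau)`` to the
    post-pulse decay of the summed open-state occupancy.

    Returns ``(tau_seconds, t_grid, open_prob)``.
    """
    from .analysis import fit_decay  # local import to avoid cycle

    n = Q_pulse.shape[0]
    p0 = np.zeros(n)
    p0[start_state] = 1.0
    p_end = p0 @ expm(Q_pulse * pulse_width)

    n_steps = int(round(horizon / dt))
    P = expm(Q_rest * dt)
    occ = np.empty((n_steps + 1, n))
    occ[0] = p_end
    for i in range(n_steps):
        occ[i + 1] = occ[i] @ P
    t = np.arange(n_steps + 1) * dt
    open_p = occ[:, list(open_idx)].sum(axis=1)
    tau, _ = fit_decay(t, open_p, baseline=0.0)
    return tau, t, open_p
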