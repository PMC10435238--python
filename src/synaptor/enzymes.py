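"""Coarse-grained CaM - CaMKII - CaN reaction network (deterministic).

The spine enzymes are modelled as a mass-action network of 17 concentration
variables driven by free spine calcium: calmodulin (CaM) in four lumped
calcium-loading states (calcium binds and unbinds in pairs at the C- and
N-terminal lobes), CaMKII monomer units that bind CaM at any loading state,
become phosphorylated while CaM-bound and can then hold activity autonomously
(P, P2) after releasing CaM, and calcineurin (CaN), which binds fully loaded
CaM4 only.  The lumped two-ion binding steps use calcium-dependent effective
rates ``adapt(a, b, c, d, Ca) = a*b / (c + d*Ca)`` (µM⁻² s⁻¹ forward, so a
forward flux is ``kf * X * Ca²``).

The enzymes are continuous and deterministic; stochasticity enters only
through the calcium input.  Three totals are conserved exactly: CaM-containing
species (30 µM), kinase-containing species (70 µM) and CaN species (20 µM).

Temperature: the backward CaMKII factor scales the dissociation steps k2, k3
and k5; the CaN association/dissociation steps carry their own forward and
backward factors.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .conditions import temperature_factors
from .params import ParameterSet, default_params

__all__ = [
    "ENZYME_SPECIES", "N_SPECIES", "adapt_rate", "enzyme_derivatives",
    "active_pair", "initial_state", "equilibrate", "conserved_totals",
]

ENZYME_SPECIES = (
    "CaM0", "CaM2C", "CaM2N", "CaM4",
    "mKCaM", "KCaM0", "KCaM2C", "KCaM2N", "KCaM4",
    "PCaM0", "PCaM2C", "PCaM2N", "PCaM4",
    "P", "P2",
    "mCaN", "CaNCaM4",
)
N_SPECIES = len(ENZYME_SPECIES)
_I = {s: i for i, s in enumerate(ENZYME_SPECIES)}

# index groups for the observables
_KCAM = [_I[s] for s in ("KCaM0", "KCaM2C", "KCaM2N", "KCaM4")]
_PCAM = [_I[s] for s in ("PCaM0", "PCaM2C", "PCaM2N", "PCaM4")]
_CAMKII_ACTIVE = _KCAM + _PCAM + [_I["P"], _I["P2"]]
_CAM_TOTAL = ([_I[s] for s in ("CaM0", "CaM2C", "CaM2N", "CaM4")]
              + _KCAM + _PCAM + [_I["CaNCaM4"]])
_KINASE_TOTAL = [_I["mKCaM"]] + _KCAM + _PCAM + [_I["P"], _I["P2"]]
_CAN_TOTAL = [_I["mCaN"], _I["CaNCaM4"]]


def adapt_rate(a: float, b: float, c: float, d: float, ca):
    """Calcium-dependent lumped rate ``a*b / (c + d*Ca)``.

    Used for the paired-calcium binding/unbinding steps of the coarse-grained
    CaM model: at Ca → 0 the backward rates reduce to the slow-lobe
    dissociation constant, and unbinding is suppressed at saturating calcium.
    """
    if min(a, b, c, d) <= 0:
        raise ValueError("adapt() constants must be positive")
    return a * b / (c + d * np.asarray(ca, dtype=float))


def enzyme_derivatives(
    state: np.ndarray,
    ca,
    T: float = 35.0,
    params: ParameterSet | None = None,
    with_ca_flux: bool = False,
):
    """Mass-action time derivatives (µM/s) of the 17 enzyme species.

    ``state`` has the species on its last axis and may carry leading batch
    axes; ``ca`` is the free calcium concentration (µM), broadcastable against
    the batch shape.  With ``with_ca_flux=True`` also returns the calcium
    consumption rate (µM/s, negative = calcium removed from the free pool; two
    ions per lumped binding step).
    """
    p = params or default_params()
    rho_k = temperature_factors(T, "CaMKII").rho_b
    rho_can = temperature_factors(T, "CaN")

    s = np.asarray(state, dtype=float)
    ca = np.asarray(ca, dtype=float)
    ca2 = ca * ca

    kf2C = adapt_rate(p["kon_1C"], p["kon_2C"], p["koff_1C"], p["kon_2C"], ca)
    kb2C = adapt_rate(p["koff_1C"], p["koff_2C"], p["koff_1C"], p["kon_2C"], ca)
    kf2N = adapt_rate(p["kon_1N"], p["kon_2N"], p["koff_1N"], p["kon_2N"], ca)
    kb2N = adapt_rate(p["koff_1N"], p["koff_2N"], p["koff_1N"], p["kon_2N"], ca)
    kfK2C = adapt_rate(p["kon_K1C"], p["kon_K2C"], p["koff_K1C"], p["kon_K2C"], ca)
    kbK2C = adapt_rate(p["koff_K1C"], p["koff_K2C"], p["koff_K1C"], p["kon_K2C"], ca)
    kfK2N = adapt_rate(p["kon_K1N"], p["kon_K2N"], p["koff_K1N"], p["kon_K2N"], ca)
    kbK2N = adapt_rate(p["koff_K1N"], p["koff_K2N"], p["koff_K1N"], p["kon_K2N"], ca)

    CaM0, CaM2C, CaM2N, CaM4 = (s[..., _I[k]] for k in
                                ("CaM0", "CaM2C", "CaM2N", "CaM4"))
    mK = s[..., _I["mKCaM"]]
    K0, K2C, K2N, K4 = (s[..., _I[k]] for k in
                        ("KCaM0", "KCaM2C", "KCaM2N", "KCaM4"))
    P0_, P2C_, P2N_, P4_ = (s[..., _I[k]] for k in
                            ("PCaM0", "PCaM2C", "PCaM2N", "PCaM4"))
    P, P2 = s[..., _I["P"]], s[..., _I["P2"]]
    mCaN, CaN4 = s[..., _I["mCaN"]], s[..., _I["CaNCaM4"]]

    # lumped paired-calcium binding fluxes (µM/s)
    F1 = kf2C * CaM0 * ca2 - kb2C * CaM2C
    F2 = kf2N * CaM0 * ca2 - kb2N * CaM2N
    F3 = kf2N * CaM2C * ca2 - kb2N * CaM4
    F4 = kf2C * CaM2N * ca2 - kb2C * CaM4
    F5 = kfK2C * K0 * ca2 - kbK2C * K2C
    F6 = kfK2N * K0 * ca2 - kbK2N * K2N
    F7 = kfK2N * K2C * ca2 - kbK2N * K4
    F8 = kfK2C * K2N * ca2 - kbK2C * K4
    # CaM <-> CaMKII binding
    G0 = p["kf_CaM0"] * CaM0 * mK - p["kb_CaM0"] * K0
    G1 = p["kf_CaM2C"] * CaM2C * mK - p["kb_CaM2C"] * K2C
    G2 = p["kf_CaM2N"] * CaM2N * mK - p["kb_CaM2N"] * K2N
    G3 = p["kf_CaM4"] * CaM4 * mK - p["kb_CaM4"] * K4
    # phosphorylation of CaM-bound kinase, proportional to the active fraction
    act = K0 + K2C + K2N + K4 + P0_ + P2C_ + P2N_ + P4_ + P + P2
    frac = act / p["mKCaM_con"]
    k1f = p["k1_camkii"] * frac
    H0, H2C, H2N, H4 = k1f * K0, k1f * K2C, k1f * K2N, k1f * K4
    # CaM release from phosphorylated kinase, autonomous states
    k2 = p["k2_camkii"] * rho_k
    R0, R2C, R2N, R4 = k2 * P0_, k2 * P2C_, k2 * P2N_, k2 * P4_
    k3 = p["k3_camkii"] * rho_k
    k5 = p["k5_camkii"] * rho_k
    # CaN <-> CaM4
    W = (p["kf_CaN"] * rho_can.rho_f * CaM4 * mCaN
         - p["kb_CaN"] * rho_can.rho_b * CaN4)

    d = np.empty_like(s)
    d[..., _I["CaM0"]] = -F1 - F2 - G0 + R0
    d[..., _I["CaM2C"]] = F1 - F3 - G1 + R2C
    d[..., _I["CaM2N"]] = F2 - F4 - G2 + R2N
    d[..., _I["CaM4"]] = F3 + F4 - G3 - W + R4
    d[..., _I["mKCaM"]] = -G0 - G1 - G2 - G3 + k3 * P
    d[..., _I["KCaM0"]] = G0 - F5 - F6 - H0
    d[..., _I["KCaM2C"]] = G1 + F5 - F7 - H2C
    d[..., _I["KCaM2N"]] = G2 + F6 - F8 - H2N
    d[..., _I["KCaM4"]] = G3 + F7 + F8 - H4
    d[..., _I["PCaM0"]] = H0 - R0
    d[..., _I["PCaM2C"]] = H2C - R2C
    d[..., _I["PCaM2N"]] = H2N - R2N
    d[..., _I["PCaM4"]] = H4 - R4
    d[..., _I["P"]] = R0 + R2C + R2N + R4 - k3 * P - p["k4_camkii"] * P + k5 * P2
    d[..., _I["P2"]] = p["k4_camkii"] * P - k5 * P2
    d[..., _I["mCaN"]] = -W
    d[..., _I["CaNCaM4"]] = W

    if with_ca_flux:
        ca_flux = -2.0 * (F1 + F2 + F3 + F4 + F5 + F6 + F7 + F8)
        return d, ca_flux
    return d


def active_pair(state: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """(active CaN, active CaMKII) in µM from an enzyme state.

    Active CaN is the CaM4-bound complex; active CaMKII sums the CaM-bound,
    phosphorylated-CaM-bound and autonomous states.
    """
    s = np.asarray(state)
    can = s[..., _I["CaNCaM4"]]
    camkii = s[..., _CAMKII_ACTIVE].sum(axis=-1)
    return can, camkii


def conserved_totals(state: np.ndarray):
    """(CaM total, kinase total, CaN total) in µM — invariants of the flow."""
    s = np.asarray(state)
    return (
        s[..., _CAM_TOTAL].sum(axis=-1),
        s[..., _KINASE_TOTAL].sum(axis=-1),
        s[..., _CAN_TOTAL].sum(axis=-1),
    )


def initial_state(params: ParameterSet | None = None) -> np.ndarray:
    """All-free initial condition: CaM0 = 30, mKCaM = 70, mCaN = 20 µM."""
    p = params or default_params()
    s = np.zeros(N_SPECIES)
    s[_I["CaM0"]] = p["CaM_con"]
    s[_I["mKCaM"]] = p["mKCaM_con"]
    s[_I["mCaN"]] = p["mCaN_con"]
    return s


def equilibrate(
    ca: float = 0.05,
    T: float = 35.0,
    duration: float = 100.0,
    params: ParameterSet | None = None,
    state0: np.ndarray | None = None,
) -> np.ndarray:
    """Relax the network at constant calcium for ``duration`` seconds."""
    p = params or default_params()
    s0 = initial_state(p) if state0 is None else np.asarray(state0, float)
    sol = solve_ivp(
        lambda _, y: enzyme_derivatives(y, ca, T, p),
        (0.0, duration), s0, method="LSODA", rtol=1e-8, atol=1e-10,
    )
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"enzyme equilibration failed: {sol.message}")
    return sol.y[:, -1]
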