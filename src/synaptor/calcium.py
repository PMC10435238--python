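"""Spine calcium mass balance.

Free spine calcium is driven by channel influx (NMDAr calcium fraction and
the three VGCC subtypes, each through the Goldman-Hodgkin-Katz flux
nonlinearity), relaxes to its 50 nM baseline, diffuses into the dendrite
(which is assumed to sit at one-third of the spine concentration, floored at
baseline), and exchanges with a generic endogenous buffer, the explicitly
modelled calmodulin pool, and — in dye mode — a Fluo-5F indicator.

The GHK expression is used for the shape of the voltage/concentration
dependence of calcium flux; its absolute scale (``ghk_scale``) is a
calibration constant fixed so that a single successful vesicle release yields
a ~3 µM calcium transient under the default conditions (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from .conditions import ExperimentalConditions
from .params import ParameterSet, default_params

__all__ = [
    "ghk_drive", "ca_current", "tau_ca_diff",
    "calcium_derivatives", "dye_mode_transform", "buffer_equilibrium",
]


def ghk_drive(v_sp, ca_i, ca_o: float, T: float,
              params: ParameterSet | None = None):
    """Normalised GHK calcium driving term (mV-equivalent), positive = influx.

    ``v_sp`` in mV, ``ca_i`` in µM, ``ca_o`` in mM, ``T`` in °C.  Zero exactly
    at the calcium Nernst potential; continuous at v = 0 through the series
    limit.  Multiplied by a channel's calcium conductance (nS) it yields the
    calcium current in pA.
    """
    p = params or default_params()
    v, ci = np.broadcast_arrays(np.asarray(v_sp, dtype=float),
                                np.asarray(ca_i, dtype=float) * 1e-3)  # µM->mM
    TK = T + 273.15
    # dimensionless voltage z F V / (R T); V in volts
    phi = p["z_Ca"] * 96485.0 * (v * 1e-3) / (p["R_gas"] * TK)
    phi = np.clip(phi, -60.0, 60.0)
    small = np.abs(phi) < 1e-4
    drive = np.empty_like(phi)
    if np.any(~small):
        ph = phi[~small]
        e = np.exp(-ph)
        drive[~small] = -p["ghk_scale"] * ph * (ci[~small] - ca_o * e) / (1.0 - e)
    if np.any(small):
        # series limit: -phi (ci - co e^{-phi})/(1-e^{-phi})
        #             = (co - ci) - phi (co + ci)/2 + O(phi^2)
        ph = phi[small]
        drive[small] = p["ghk_scale"] * ((ca_o - ci[small])
                                         - ph * 0.5 * (ca_o + ci[small]))
    return drive if drive.shape else float(drive)


def ca_current(g_ca, v_sp, ca_i, conditions: ExperimentalConditions):
    """Calcium current (pA, positive = influx) for conductance ``g_ca`` nS."""
    return g_ca * ghk_drive(v_sp, ca_i, conditions.ca_o,
                            conditions.temperature, conditions.params)


def tau_ca_diff(params: ParameterSet | None = None) -> float:
    """Spine-to-dendrite calcium diffusion time constant (s), from geometry."""
    p = params or default_params()
    return (p["Vol_sp"] / (2.0 * p["D_Ca"] * p["D_neck"])
            + p["L_neck"] ** 2 / (2.0 * p["D_Ca"]))


def buffer_equilibrium(ca, params: ParameterSet | None = None):
    """Bound generic-buffer concentration at equilibrium with free calcium."""
    p = params or default_params()
    kd = p["koff_buff"] / p["kon_buff"]
    ca = np.asarray(ca, dtype=float)
    return p["buff_con"] * ca / (ca + kd)


def calcium_derivatives(
    ca, buff_ca, dye_ca,
    i_ca_total,
    conditions: ExperimentalConditions,
    enzyme_ca_flux=0.0,
):
    """(dCa/dt, dBuff/dt, dDye/dt) in µM/s.

    ``i_ca_total`` is the summed channel calcium current in pA (positive
    influx); ``enzyme_ca_flux`` the calcium exchange with the CaM network
    (µM/s, negative = bound by CaM).
    """
    p = conditions.params
    ca = np.asarray(ca, dtype=float)
    conv = 1e9 / (2.0 * 96485.0 * p["Vol_sp"])   # pA -> µM/s in the spine head
    d_buff = p["kon_buff"] * (p["buff_con"] - buff_ca) * ca \
        - p["koff_buff"] * buff_ca
    if conditions.dye_mode:
        d_dye = p["kon_dye"] * (p["dye_con"] - dye_ca) * ca \
            - p["koff_dye"] * dye_ca
    else:
        d_dye = np.zeros_like(ca)
    d_ca = (
        (p["Ca_infty"] - ca) / p["tau_Ca"]
        + np.asarray(i_ca_total) * conv
        + (np.maximum(p["Ca_infty"], ca / 3.0) - ca) / tau_ca_diff(p)
        - d_buff - d_dye
        + enzyme_ca_flux
    )
    return d_ca, d_buff, d_dye


def dye_mode_transform(conditions: ExperimentalConditions) -> ExperimentalConditions:
    """Conditions as seen by the model in a dye experiment.

    Imaging lasers heat the tissue, so channel kinetics run at an elevated
    effective temperature, and the BaP injection is damped; both published
    adjustments are applied here.  The dye species itself is integrated by the
    engine when ``dye_mode`` is set.
    """
    if not conditions.dye_mode:
        return conditions
    p = conditions.params
    new_params = p.replace(I_amp=p["I_amp"] * p["dye_bap_factor"])
    return conditions.with_(
        temperature=conditions.temperature + p["dye_temp_shift"],
        params=new_params,
    )
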