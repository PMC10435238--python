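"""Fixed model constants.

All constants live in a single flat :class:`ParameterSet` keyed by the symbol
names used throughout the neurophysiology literature for this synapse model
(presynaptic vesicle pools, three-compartment electrical model, AMPAr / NMDAr /
GABA(A)r / VGCC / SK channels, spine calcium handling, the coarse-grained
CaM-CaMKII-CaN network, and the plasticity readout).

Internal unit system
--------------------
time               s
voltage            mV
conductance        nS
current            pA          (nS * mV = pA)
capacitance        pF
intracellular conc µM
extracellular conc mM
rates              s⁻¹ (binding rates µM⁻¹ s⁻¹); constants printed in ms⁻¹ in
                   the sources (soma spike gates, VGCC gates) are converted to
                   s⁻¹ where they are evaluated.

A handful of magnitudes are not recoverable from the published tables
(single-channel calcium conductances for the VGCC subtypes, the SK conductance,
the GHK flux scale, and the somatic current-injection amplitude).  These are
calibration constants: they were fixed once, by the calibration procedure in
``scripts/calibrate.py`` (soma action potential overshooting 0 mV, ~60 mV spine
depolarisation per back-propagating action potential, ~3 µM peak spine calcium
for a single successful vesicle release), and are stored here like any other
constant.
"""

from __future__ import annotations

from typing import Dict

__all__ = ["DEFAULT_PARAMS", "ParameterSet", "default_params"]


class ParameterSet(dict):
    """Flat ``{symbol: value}`` mapping with attribute access.

    A plain dict subclass so it round-trips losslessly through YAML/JSON.
    """

    def __getattr__(self, name: str):
        try:
            return self[name]
        except KeyError as err:  # pragma: no cover - defensive
            raise AttributeError(name) from err

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict.__getitem__(self, k) for k in ())  # pragma: no cover

    def replace(self, **overrides) -> "ParameterSet":
        """Return a new set with ``overrides`` applied (unknown keys rejected)."""
        unknown = set(overrides) - set(self)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        new = ParameterSet(self)
        new.update(overrides)
        return new


#: every fixed constant of the model, in the internal unit system
DEFAULT_PARAMS: Dict[str, float] = {
    # ------------------------------------------------------------------
    # presynaptic vesicle pools and release (stochastic + deterministic)
    # ------------------------------------------------------------------
    "D0": 25,            # initial/maximal docked pool size
    "R0": 30,            # initial/maximal reserve pool size
    "tau_D": 5.0,        # s, reserve -> docked refill timescale
    "tau_R": 45.0,       # s, docked -> reserve mixing timescale
    "tau_R_ref": 40.0,   # s, reserve replenishment timescale
    "s_rel": 2.0,        # Hill slope of the release-probability sigmoid
    "h_rel_base": 0.654,     # release threshold sigmoid: base
    "h_rel_amp": 1.349,      # amplitude
    "h_rel_slope": 4.0,      # mM⁻¹
    "h_rel_mid": 1.708,      # mM
    "tau_pre": 0.02,     # s, presynaptic calcium resource decay
    "tau_rec_pre": 20.0,  # s, jump-size recovery
    "delta_ca_pre": 4e-4,  # jump-size depression factor
    # ------------------------------------------------------------------
    # glutamate / GABA transmitter pulse
    # ------------------------------------------------------------------
    "glu_width": 1e-3,   # s, cleft transmitter pulse duration
    "glu_amp": 1e3,      # µM, mean cleft glutamate concentration
    "glu_cv": 0.52,      # gamma-distribution parameter of amplitude variability
    # ------------------------------------------------------------------
    # passive electrical properties (three compartments)
    # ------------------------------------------------------------------
    "E_leak": -70.0,     # mV
    "C_sp": 2.8e-3,      # pF, spine head capacitance
    "C_dend": 52.77,     # pF
    "C_soma": 16.96,     # pF
    "g_neck": 3.92,      # nS, spine neck axial conductance
    "gL_sp": 1.86e-6,    # nS
    "gL_dend": 3.51e-2,  # nS
    "gL_soma": 15.0,     # nS
    "g_diff": 50.0,      # nS, dendrite axial conductance
    "Vol_sp": 0.03,      # µm³, spine head volume
    "A_sp": 0.466,       # µm², spine head membrane area
    "D_Ca": 333.8,       # µm² s⁻¹, calcium diffusion coefficient
    "D_neck": 0.1,       # µm, spine neck diameter
    "L_neck": 0.2,       # µm, spine neck length
    # ------------------------------------------------------------------
    # soma Na/K spike currents and BaP machinery
    # ------------------------------------------------------------------
    "gamma_Na": 800.0,   # nS
    "gamma_K": 40.0,     # nS
    "Erev_Na": 50.0,     # mV
    "Erev_K": -90.0,     # mV
    "I_amp": 2500.0,     # pA, somatic injection amplitude (calibrated)
    "delta_inj": 2e-3,   # s, somatic injection duration (calibrated)
    "delta_decay": 1.727e-5,  # BaP-efficiency attenuation step factor
    "delta_aux": 2.304e-5,    # auxiliary attenuation step factor
    "tau_rec_bap": 2.0,       # s, recovery of the BaP efficiency resource
    "tau_rec_age": 0.5,       # s, recovery of the age attenuation resource
    # use-rate scale applied to the attenuation steps: the published step
    # factors are coupled to the injected current; the product
    # delta * I_amp * delta_inj is the physically meaningful per-spike use,
    # calibrated once against the published use-dependent attenuation
    # (dendritic BaP amplitude ~85% at the 30th of 30 pairings at 5 Hz).
    "bap_use_scale": 1.0e6,   # dimensionless injection drive on the steps
    "phi_dist_base": 0.1,
    "phi_dist_amp": 1.4,
    "phi_dist_slope": 0.02,   # µm⁻¹
    "phi_dist_mid": 230.3,    # µm
    "age_step_amp": 1.391e-4,
    "age_step_slope": 0.135,  # day⁻¹
    "age_step_mid": 16.482,   # days
    "tau_V_evoke": 0.04,      # s, EPSP-summation proxy decay
    "delta_delay_AP": 0.015,  # s, EPSP -> evoked-AP latency
    "n_syn_evoke": 25,        # afferent synapses in the evoked-AP test
    "evoke_threshold": 0.8,   # success fraction required to evoke an AP
    # ------------------------------------------------------------------
    # AMPAr (16-state chain, 120 receptors)
    # ------------------------------------------------------------------
    "N_AMPA": 120,
    "Erev_AMPA": 0.0,     # mV
    "gamma_A2": 0.0155,   # nS
    "gamma_A3": 0.026,    # nS
    "gamma_A4": 0.0365,   # nS
    "ampa_k1": 16.0,      # µM⁻¹ s⁻¹, glutamate binding
    "ampa_k_1": 7400.0,   # s⁻¹, unbinding (closed row)
    "ampa_k_2": 0.41,     # s⁻¹, unbinding (desensitised row)
    "ampa_alpha": 2600.0,  # s⁻¹, channel closing
    "ampa_beta": 9600.0,   # s⁻¹, channel opening
    "ampa_delta_1": 1500.0,  # s⁻¹, desensitisation from C1
    "ampa_delta_2": 170.0,   # s⁻¹, desensitisation from C2..C4/O-levels
    "ampa_delta_0": 0.003,   # s⁻¹, desensitisation from C0
    "ampa_gamma_1": 9.1,     # s⁻¹, recovery D1 -> C1
    "ampa_gamma_2": 42.0,    # s⁻¹, recovery D2..D4 -> C2..C4
    "ampa_gamma_0": 0.83,    # s⁻¹, recovery D0 -> C0
    # ------------------------------------------------------------------
    # NMDAr (GluN2A chain; GluN2B = printed fractions of it)
    # ------------------------------------------------------------------
    "N_NMDA": 15,
    "Erev_NMDA": 0.0,    # mV
    "f_Ca_NMDA": 0.1,    # fraction of NMDAr current carried by calcium
    "nmda_ka": 34.0,     # µM⁻¹ s⁻¹
    "nmda_kb": 17.0,     # µM⁻¹ s⁻¹
    "nmda_kc": 127.0,    # s⁻¹
    "nmda_kd": 580.0,    # s⁻¹
    "nmda_ke": 2508.0,   # s⁻¹
    "nmda_kf": 3449.0,   # s⁻¹
    "nmda_k_f": 662.0,   # s⁻¹
    "nmda_k_e": 2167.0,  # s⁻¹
    "nmda_k_d": 2610.0,  # s⁻¹
    "nmda_k_c": 161.0,   # s⁻¹
    "nmda_k_b": 120.0,   # s⁻¹
    "nmda_k_a": 60.0,    # s⁻¹
    "glun2b_fwd_frac": 0.25,   # GluN2B forward rates as fraction of GluN2A
    "glun2b_bwd_frac": 0.23,   # GluN2B backward rates as fraction of GluN2A
    "mg_K0": 3.57,       # mM, magnesium block affinity scale
    "mg_slope": 0.062,   # mV⁻¹, magnesium block voltage sensitivity
    "gamma_nmda_base": 33.949,  # pS, conductance sigmoid floor
    "gamma_nmda_amp": 58.388,   # pS
    "gamma_nmda_slope": 4.0,    # mM⁻¹
    "gamma_nmda_mid": 2.701,    # mM
    "r_age_base": 0.507,
    "r_age_amp": 0.964,
    "r_age_slope": 0.099,   # day⁻¹
    "r_age_mid": 25.102,    # days
    "r_age_noise_sd": 0.05,
    # ------------------------------------------------------------------
    # GABA(A)r (5-state chain, 34 receptors)
    # ------------------------------------------------------------------
    "N_GABA": 34,
    "gamma_GABA": 0.036,   # nS
    "gaba_rb1": 20.0,      # µM⁻¹ s⁻¹
    "gaba_ru1": 4.6e3,     # s⁻¹
    "gaba_rb2": 10.0,      # µM⁻¹ s⁻¹
    "gaba_ru2": 9.2e3,     # s⁻¹
    "gaba_ro1": 3.3e3,     # s⁻¹
    "gaba_ro2": 10.6e3,    # s⁻¹
    "gaba_rc1": 400.0,     # s⁻¹
    "gaba_rc2": 9.8e3,     # s⁻¹
    "erev_cl_base": -92.649,   # mV, adult chloride reversal asymptote
    "erev_cl_amp": 243.515,    # mV
    "erev_cl_slope": 0.091,    # day⁻¹
    "erev_cl_mid": 0.691,      # days
    # ------------------------------------------------------------------
    # VGCC (T/R/L, 3 channels per subtype) - gate rates in electrical.py
    # ------------------------------------------------------------------
    "N_VGCC": 3,
    # single-channel calcium conductances.  The published table magnitudes are
    # exponent-garbled; the 12/17/27 ratios are kept and the absolute scale is
    # set by the physiological pS range together with the GHK flux calibration
    # (see ghk_scale below).
    "gamma_CaT": 12e-3,    # nS
    "gamma_CaR": 17e-3,    # nS
    "gamma_CaL": 27e-3,    # nS
    # ------------------------------------------------------------------
    # SK channel (deterministic)
    # ------------------------------------------------------------------
    "N_SK": 15,
    "gamma_SK": 0.01,     # nS (published magnitude exponent-garbled; single
                          # SK channel conductance ~10 pS)
    "Erev_SK": -90.0,     # mV
    "h_SK": 0.333,        # µM, half-activation calcium
    "sigma_SK": 6.0,      # Hill slope
    "tau_SK": 6.3e-3,     # s
    # ------------------------------------------------------------------
    # spine calcium handling
    # ------------------------------------------------------------------
    "Ca_infty": 0.05,     # µM, resting free calcium
    "tau_Ca": 1e-2,       # s, calcium extrusion/decay timescale
    "kon_buff": 247.0,    # µM⁻¹ s⁻¹, generic endogenous buffer on-rate
    "koff_buff": 524.0,   # s⁻¹
    "buff_con": 62.0,     # µM, generic buffer concentration
    "kon_dye": 800.0,     # µM⁻¹ s⁻¹, Fluo-5F on-rate
    "koff_dye": 1264.0,   # s⁻¹ (Kd 1.58 µM)
    "dye_con": 200.0,     # µM, Fluo-5F concentration in dye mode
    "dye_temp_shift": 10.0,   # °C, laser-heating surrogate in dye mode
    "dye_bap_factor": 0.8,    # BaP injection amplitude reduction in dye mode
    "Faraday": 96.485,    # C mmol⁻¹ (96485 C mol⁻¹)
    "R_gas": 8.314,       # J K⁻¹ mol⁻¹
    "z_Ca": 2.0,
    # GHK flux scale (mV-equivalent driving force per mM): single calibrated
    # constant converting the normalised GHK flux into pA per nS of calcium
    # conductance, fixed so a single successful vesicle release yields ~3 µM
    # peak spine calcium at the default conditions.
    "ghk_scale": 0.85,
    # ------------------------------------------------------------------
    # enzyme network concentrations (conserved totals)
    # ------------------------------------------------------------------
    "CaM_con": 30.0,      # µM total calmodulin
    "mKCaM_con": 70.0,    # µM total CaMKII (monomer units)
    "mCaN_con": 20.0,     # µM total calcineurin
    # CaM-Ca lumped two-ion binding (coarse-grained constants)
    "kon_1C": 5.0, "kon_2C": 10.0, "koff_1C": 50.0, "koff_2C": 10.0,
    "kon_1N": 100.0, "kon_2N": 200.0, "koff_1N": 2000.0, "koff_2N": 500.0,
    # KCaM-Ca lumped two-ion binding
    "kon_K1C": 44.0, "kon_K2C": 44.0, "koff_K1C": 33.0, "koff_K2C": 0.8,
    "kon_K1N": 76.0, "kon_K2N": 76.0, "koff_K1N": 300.0, "koff_K2N": 20.0,
    # CaM <-> CaMKII binding
    "kf_CaM0": 0.0038, "kb_CaM0": 5.5,
    "kf_CaM2C": 0.92, "kb_CaM2C": 6.8,
    "kf_CaM2N": 0.12, "kb_CaM2N": 1.7,
    "kf_CaM4": 30.0, "kb_CaM4": 1.5,
    # CaMKII phosphorylation cascade
    "k1_camkii": 12.6,        # s⁻¹, KCaM -> PCaM (times activated fraction)
    "k2_camkii": 0.33,        # s⁻¹, PCaM -> P + CaM
    "k3_camkii": 4 * 0.17,    # s⁻¹, P -> mKCaM
    "k4_camkii": 4 * 0.041,   # s⁻¹, P -> P2
    "k5_camkii": 8 * 0.017,   # s⁻¹, P2 -> P
    # CaN <-> CaM4
    "kf_CaN": 10.75,     # µM⁻¹ s⁻¹
    "kb_CaN": 0.02,      # s⁻¹
    # ------------------------------------------------------------------
    # plasticity readout (regions, activations, Markov chain)
    # ------------------------------------------------------------------
    "a_D": 100.0,        # a.u. s⁻¹, rise inside the LTD region
    "a_P": 200.0,        # a.u. s⁻¹, rise inside the LTP region
    "b_D": 2e-2,         # s⁻¹, decay outside the LTD region
    "b_P": 0.1,          # s⁻¹, decay outside the LTP region
    "t_D": 18.0,         # s, LTD transition time constant
    "t_P": 13.0,         # s, LTP transition time constant
    "K_D": 8e4,          # a.u., LTD rate half-occupation
    "K_P": 1.3e4,        # a.u., LTP rate half-occupation
    "n_processes": 100,  # plasticity Markov chain population
    "readout_dt": 0.01,  # s, grid on which the readout consumes enzymes
}

#: LTP region vertices in the (CaN, CaMKII) plane, µM (a closed rectangle)
LTP_VERTICES = [(6.35, 1.4), (10.0, 1.4), (10.0, 29.5), (6.35, 29.5)]

#: LTD region vertices as published (unordered); canonicalised in `readout`
LTD_VERTICES = [
    (6.35, 1.4), (6.35, 23.25), (6.35, 29.5), (1.85, 11.32),
    (1.85, 23.25), (3.76, 1.4), (5.65, 29.5),
]


def default_params() -> ParameterSet:
    """Return a fresh mutable copy of the default parameter set."""
    return ParameterSet(DEFAULT_PARAMS)
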