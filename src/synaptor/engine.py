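"""Hybrid stochastic simulation engine.

The synapse model is a piecewise-deterministic Markov process: continuous
variables (compartment voltages, spike gates, calcium, buffers, the enzyme
network, attenuation resources) flow deterministically between the discrete
transitions of the channel populations and vesicle pools.  The engine
advances the joint state on an event-segmented time grid:

* Receptor populations (AMPAr, NMDAr, GABAr) have ligand-dependent but
  voltage-independent rate matrices, so within any segment of constant
  transmitter concentration their per-channel transition probabilities over a
  step are computed *exactly* as matrix exponentials; state counts are then
  resampled multinomially (exact marginal distributions on the step grid, with
  no small-rate approximation).
* VGCC activation/inactivation gates are two-state chains with
  voltage-dependent rates; they use the exact two-state transition
  probability with rates frozen over the (25 µs) step.
* The continuous subsystem advances with exponential-Euler updates
  (unconditionally stable for the stiff spine compartment) and an RK2 step
  for the enzyme network.

Step sizes are tiered by activity: 25 µs inside a window after each spike
event, 0.25 ms while receptor tails are still active, 0.5 ms during
quiescence.  After the last transient the enzyme network alone is integrated
(LSODA) to the horizon, and the geometric readout consumes the recorded
CaN/CaMKII trajectories on its 10 ms grid.

Every random draw derives from the run seed through named child streams
(presynaptic release, evoked APs, subunit assignment, channel gating, the
plasticity chain), so switching one stochastic source to its mean-field mode
does not perturb the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from . import channels as ch
from . import readout as ro
from .calcium import dye_mode_transform, ghk_drive, buffer_equilibrium, tau_ca_diff
from .conditions import ExperimentalConditions, erev_chloride, gamma_nmda, \
    nmda_subunit_counts, temperature_factors
from .electrical import (adaptation_derivatives, evoked_ap_times, g_bap_adapt,
                         soma_gate_rates, soma_gate_steady)
from .enzymes import (active_pair, enzyme_derivatives, equilibrate)
from .presynapse import simulate_presynapse
from .protocols import Protocol
from .analysis import summarize_outcomes

__all__ = ["RunConfig", "SimulationResult", "simulate", "batch_run"]


@dataclass
class RunConfig:
    """Run settings for the hybrid engine."""

    seed: int = 0
    n_samples: int = 1
    warmup: float = 100.0        # s of enzyme relaxation before the protocol
    t_end: Optional[float] = None  # horizon; default protocol end + tail
    tail: float = 400.0          # s of readout horizon after the protocol
    output_dt: float = 1e-3      # s, observable recording grid
    readout_dt: float = 0.01     # s, grid the readout consumes
    dt_hot: float = 2.5e-5       # s, step inside the post-event window
    dt_mid: float = 2.5e-4       # s, step while receptor tails are active
    dt_quiet: float = 5e-4       # s, step during quiescence
    hot_window: float = 0.03     # s of fine stepping after each spike event
    mid_window: float = 0.4      # s of medium stepping after each spike event
    main_pad: float = 1.0        # s of full simulation kept after last event
    record_channels: bool = True
    check_conservation: bool = False  # assert population invariants per step

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class SimulationResult:
    """Batch simulation output.

    ``records`` maps observable name to an (n_samples, n_t) array on the
    ``t`` grid; CaN/CaMKII activities live on the coarser ``t_readout`` grid
    which extends to the full readout horizon.
    """

    t: np.ndarray
    records: Dict[str, np.ndarray]
    t_readout: np.ndarray
    can: np.ndarray
    camkii: np.ndarray
    weights: np.ndarray
    act_p: np.ndarray
    act_d: np.ndarray
    chain: ro.PlasticityChain
    presyn: list
    protocol: Protocol
    conditions: ExperimentalConditions
    config: RunConfig

    @property
    def outcome(self):
        return summarize_outcomes(self.weights)

    def save_hdf5(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["protocol"] = self.protocol.name
            f.attrs["n_samples"] = self.config.n_samples
            f.attrs["seed"] = self.config.seed
            f.create_dataset("t", data=self.t)
            for k, v in self.records.items():
                f.create_dataset(k, data=v)
            f.create_dataset("t_readout", data=self.t_readout)
            f.create_dataset("CaN_active", data=self.can)
            f.create_dataset("CaMKII_active", data=self.camkii)
            f.create_dataset("weights", data=self.weights)


# ----------------------------------------------------------------------
# event segmentation
# ----------------------------------------------------------------------

def _build_segments(glu_events, inj_events, t_stop, cfg: RunConfig):
    """Split [0, t_stop] into segments of constant transmitter amplitude,
    constant injection and a single step-size tier.

    ``glu_events``: list of (t_on, t_off, amp_vector); ``inj_events``: list of
    (t_on, t_off, sample_index or None for all).  Returns a list of
    ``(t0, t1, glu_amp (n,), inj_mask (n,), dt)``.
    """
    edges = {0.0, t_stop}
    spike_times = []
    for t_on, t_off, _ in glu_events:
        if t_on < t_stop:
            edges.update((t_on, min(t_off, t_stop)))
            spike_times.append(t_on)
    for t_on, t_off, _ in inj_events:
        if t_on < t_stop:
            edges.update((t_on, min(t_off, t_stop)))
            spike_times.append(t_on)
    for ts in list(spike_times):
        for w in (cfg.hot_window, cfg.mid_window):
            if ts + w < t_stop:
                edges.add(ts + w)
    edges = np.array(sorted(e for e in edges if 0.0 <= e <= t_stop))
    spike_times = np.array(sorted(set(spike_times))) if spike_times else \
        np.array([])

    segments = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a < 1e-12:
            continue
        mid = 0.5 * (a + b)
        # tier from time since the most recent spike event
        if spike_times.size:
            k = np.searchsorted(spike_times, mid) - 1
            since = mid - spike_times[k] if k >= 0 else np.inf
        else:
            since = np.inf
        if since <= cfg.hot_window:
            dt = cfg.dt_hot
        elif since <= cfg.mid_window:
            dt = cfg.dt_mid
        else:
            dt = cfg.dt_quiet
        segments.append([a, b, None, None, dt])

    # attach constant transmitter amplitude and injection per segment
    for seg in segments:
        mid = 0.5 * (seg[0] + seg[1])
        amp = None
        for t_on, t_off, amps in glu_events:
            if t_on <= mid < t_off:
                amp = amps if amp is None else amp + amps
        seg[2] = amp
        seg[3] = [who for t_on, t_off, who in inj_events if t_on <= mid < t_off]
    return segments


# ----------------------------------------------------------------------
# population stepping helpers
# ----------------------------------------------------------------------

def _transition_matrix(Q: np.ndarray, dt: float) -> np.ndarray:
    P = expm(Q * dt)
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=-1, keepdims=True)
    return P


def _step_population(counts, P, rng: Optional[np.random.Generator]):
    """Advance population counts one step with transition matrix ``P``.

    ``counts``: (n, S) integers (stochastic) or floats (mean-field);
    ``P``: (S, S) shared or (n, S, S) per-sample.  With ``rng=None`` the
    update is the expected-occupancy propagation under the same matrix.
    The stochastic update draws one batched multinomial per origin state
    (channels are conditionally independent given the rate matrix), which is
    exact in distribution on the step grid.
    """
    if rng is None:
        if P.ndim == 2:
            return counts @ P
        return np.einsum("ns,nst->nt", counts, P)
    pvals = P[None, :, :] if P.ndim == 2 else P
    # out[i, j, :] ~ Multinomial(counts[i, j], P[j]); sum over origins j
    out = rng.multinomial(counts, pvals)
    return out.sum(axis=1)


def _step_two_state_gates(state, alpha, beta, dt, rng):
    """Exact one-step update of independent two-state gates.

    ``state``: (n, k) booleans (stochastic) or (n,) open-probabilities
    (mean-field).  ``alpha``/``beta``: (n,) opening/closing rates.
    """
    lam = alpha + beta
    pinf = np.where(lam > 0, alpha / np.where(lam > 0, lam, 1.0), 0.0)
    decay = np.exp(-lam * dt)
    if rng is None:
        return pinf + (state - pinf) * decay
    p_open = pinf[:, None] + (state.astype(float) - pinf[:, None]) * decay[:, None]
    return rng.random(state.shape) < p_open


# ----------------------------------------------------------------------
# the simulation proper
# ----------------------------------------------------------------------

def simulate(
    protocol: Protocol,
    conditions: ExperimentalConditions | None = None,
    config: RunConfig | None = None,
) -> SimulationResult:
    """Simulate ``config.n_samples`` independent samples of one protocol.

    All samples share the protocol's spike times and are advanced together
    (vectorised); every sample has independent stochastic release, channel
    gating, receptor-subunit assignment and plasticity-chain noise.
    """
    cond = dye_mode_transform(conditions or ExperimentalConditions())
    cfg = config or RunConfig()
    p = cond.params
    n = cfg.n_samples
    T = cond.temperature

    ss = np.random.SeedSequence(cfg.seed)
    s_pre, s_evoke, s_subunit, s_chan, s_chain = ss.spawn(5)
    rng_chan = np.random.default_rng(s_chan)
    rng_chain = (None if cond.is_deterministic("plasticity")
                 else np.random.default_rng(s_chain))

    # ---------------- presynaptic pass (independent of postsynaptic state)
    pre_rngs = [np.random.default_rng(s) for s in s_pre.spawn(max(n, 1))]
    presyn = [simulate_presynapse(protocol.pre_times, cond, pre_rngs[i])
              for i in range(n)]
    n_pre = protocol.pre_times.size
    glu_amps = (np.stack([tr.glu_amp for tr in presyn])
                if n_pre else np.zeros((n, 0)))

    # ---------------- postsynaptic spike times (shared + per-sample evoked)
    post_lists: List[np.ndarray] = [protocol.post_times for _ in range(n)]
    if cond.evoked_ap_enabled and n_pre:
        ev_rngs = [np.random.default_rng(s) for s in s_evoke.spawn(n)]
        for i in range(n):
            ev = evoked_ap_times(protocol.pre_times, presyn[i].docked,
                                 cond, ev_rngs[i])
            post_lists[i] = np.sort(np.concatenate([post_lists[i], ev]))

    last_event = 0.0
    if n_pre:
        last_event = protocol.pre_times[-1] + p["glu_width"]
    for pl in post_lists:
        if pl.size:
            last_event = max(last_event, pl[-1] + p["delta_inj"])
    t_end = cfg.t_end if cfg.t_end is not None else last_event + cfg.tail
    t_main = min(t_end, last_event + cfg.main_pad)

    # ---------------- event lists
    glu_events = [(protocol.pre_times[i], protocol.pre_times[i] + p["glu_width"],
                   glu_amps[:, i]) for i in range(n_pre)]
    inj_events = []
    if any(pl.size for pl in post_lists):
        if all(np.array_equal(pl, post_lists[0]) for pl in post_lists):
            for tp in post_lists[0]:
                inj_events.append((tp, tp + p["delta_inj"], None))
        else:
            for i, pl in enumerate(post_lists):
                for tp in pl:
                    inj_events.append((tp, tp + p["delta_inj"], i))

    segments = _build_segments(glu_events, inj_events, t_main, cfg)

    # ---------------- initial state
    EL = p["E_leak"]
    v_sp = np.full(n, EL)
    v_dend = np.full(n, EL)
    v_soma = np.full(n, EL)
    m0, h0, n0_ = soma_gate_steady(EL)
    gm = np.full(n, m0); gh = np.full(n, h0); gn = np.full(n, n0_)
    lam = np.ones(n); lam_aux = np.ones(n); lam_age = np.ones(n)
    ca = np.full(n, p["Ca_infty"])
    buff = np.full(n, float(buffer_equilibrium(p["Ca_infty"], p)))
    dye = np.zeros(n)
    if cond.dye_mode:
        kd_dye = p["koff_dye"] / p["kon_dye"]
        dye[:] = p["dye_con"] * p["Ca_infty"] / (p["Ca_infty"] + kd_dye)
    msk = np.zeros(n)
    enz0 = equilibrate(p["Ca_infty"], T, cfg.warmup, p) if cfg.warmup > 0 \
        else equilibrate(p["Ca_infty"], T, 1e-6, p)
    E = np.tile(enz0, (n, 1))

    det_ampa = cond.is_deterministic("ampa")
    det_nmda = cond.is_deterministic("nmda")
    det_gaba = cond.is_deterministic("gaba")
    det_vgcc = cond.is_deterministic("vgcc")

    # receptor populations
    dtype_a = float if det_ampa else np.int64
    ampa = np.zeros((n, 16), dtype=dtype_a)
    ampa[:, 0] = p["N_AMPA"]
    rng_sub = np.random.default_rng(s_subunit)
    noise = np.zeros(n) if det_nmda else rng_sub.standard_normal(n)
    counts_2a = np.zeros(n, dtype=int); counts_2b = np.zeros(n, dtype=int)
    for i in range(n):
        counts_2a[i], counts_2b[i] = nmda_subunit_counts(
            cond.age, noise[i], int(p["N_NMDA"]))
    dtype_n = float if det_nmda else np.int64
    nmda_a = np.zeros((n, 7), dtype=dtype_n); nmda_a[:, 0] = counts_2a
    nmda_b = np.zeros((n, 7), dtype=dtype_n); nmda_b[:, 0] = counts_2b
    dtype_g = float if det_gaba else np.int64
    gaba = np.zeros((n, 5), dtype=dtype_g)
    gaba[:, 0] = p["N_GABA"]

    # VGCC gates: stationary at rest
    n_vgcc = int(p["N_VGCC"])
    if det_vgcc:
        mT = np.full(n, float(ch._t_type_minf(EL)))
        hT = np.full(n, float(ch._t_type_hinf(EL)))
        mR = np.full(n, float(ch._r_type_minf(EL)))
        hR = np.full(n, float(ch._r_type_hinf(EL)))
        vgcc_l = np.zeros((n, 3)); vgcc_l[:, 0] = n_vgcc
    else:
        mT = rng_chan.random((n, n_vgcc)) < ch._t_type_minf(EL)
        hT = rng_chan.random((n, n_vgcc)) < ch._t_type_hinf(EL)
        mR = rng_chan.random((n, n_vgcc)) < ch._r_type_minf(EL)
        hR = rng_chan.random((n, n_vgcc)) < ch._r_type_hinf(EL)
        vgcc_l = np.zeros((n, 3), dtype=np.int64); vgcc_l[:, 0] = n_vgcc

    erev_cl = erev_chloride(cond.age)
    g_nmda_unit = gamma_nmda(cond.ca_o) * 1e-3          # pS -> nS
    rho_sk = temperature_factors(T, "SK")
    rho_v = temperature_factors(T, "VGCC")
    conv_ca = 1e9 / (2.0 * 96485.0 * p["Vol_sp"])       # pA -> µM/s
    tau_diff = tau_ca_diff(p)
    phi_d = g_bap_adapt(1.0, cond.d_soma, p) / p["g_diff"]

    # cached T/R-type gate constants (rates in s⁻¹): alpha = inf/tau * rho_f,
    # beta = (1-inf)/tau * rho_b, with the voltage-independent tau of each gate
    _gf = {
        "Tm": (ch._t_type_minf, 1e3 / ch._TAU_M_T),
        "Th": (ch._t_type_hinf, 1e3 / ch._TAU_H_T),
        "Rm": (ch._r_type_minf, 1e3 / ch._TAU_M_R),
        "Rh": (ch._r_type_hinf, 1e3 / ch._TAU_H_R),
    }

    def _gate_ab(name, v):
        inf_fn, inv_tau = _gf[name]
        inf = inf_fn(v)
        return inf * inv_tau * rho_v.rho_f, (1.0 - inf) * inv_tau * rho_v.rho_b

    # ---------------- recording buffers
    t_out = np.arange(0.0, t_main + cfg.output_dt * 0.5, cfg.output_dt)
    rec_names = ["v_sp", "v_dend", "v_soma", "ca"]
    if cond.dye_mode:
        rec_names.append("dye")
    if cfg.record_channels:
        rec_names += ["ampa_open", "nmda_open", "gaba_open", "vgcc_open",
                      "lam", "lam_age"]
    rec = {k: np.zeros((t_out.size, n)) for k in rec_names}
    t_ro = np.arange(0.0, t_end + cfg.readout_dt * 0.5, cfg.readout_dt)
    can_tr = np.zeros((t_ro.size, n))
    kii_tr = np.zeros((t_ro.size, n))
    cam_tr = np.zeros((t_ro.size, n))   # calcium-bound free CaM

    i_out = 0
    i_ro = 0

    def _record(tcur):
        nonlocal i_out, i_ro
        while i_out < t_out.size and t_out[i_out] <= tcur + 1e-12:
            rec["v_sp"][i_out] = v_sp
            rec["v_dend"][i_out] = v_dend
            rec["v_soma"][i_out] = v_soma
            rec["ca"][i_out] = ca
            if cond.dye_mode:
                rec["dye"][i_out] = dye
            if cfg.record_channels:
                rec["ampa_open"][i_out] = ampa[:, list(ch.AMPA_OPEN)].sum(axis=1)
                rec["nmda_open"][i_out] = (
                    nmda_a[:, list(ch.NMDA_OPEN)].sum(axis=1)
                    + nmda_b[:, list(ch.NMDA_OPEN)].sum(axis=1))
                rec["gaba_open"][i_out] = gaba[:, list(ch.GABA_OPEN)].sum(axis=1)
                rec["vgcc_open"][i_out] = _vgcc_open()
                rec["lam"][i_out] = lam
                rec["lam_age"][i_out] = lam_age
            i_out += 1
        while i_ro < t_ro.size and t_ro[i_ro] <= tcur + 1e-12:
            c_act, k_act = active_pair(E)
            can_tr[i_ro] = c_act
            kii_tr[i_ro] = k_act
            cam_tr[i_ro] = E[:, 1] + E[:, 2] + E[:, 3]
            i_ro += 1

    def _vgcc_open():
        if det_vgcc:
            return (n_vgcc * mT * hT + n_vgcc * mR * hR
                    + vgcc_l[:, 1] + vgcc_l[:, 2])
        return ((mT & hT).sum(axis=1) + (mR & hR).sum(axis=1)
                + vgcc_l[:, 1] + vgcc_l[:, 2])

    # transition-matrix caches for transmitter-free segments
    Q0 = {
        "ampa": ch.ampar_Q(0.0, T, p),
        "nmda_a": ch.nmdar_Q(0.0, T, "GluN2A", p),
        "nmda_b": ch.nmdar_Q(0.0, T, "GluN2B", p),
        "gaba": ch.gabar_Q(0.0, T, p),
    }
    P0_cache: Dict = {}

    def _P0(name, dt):
        key = (name, round(dt, 10))
        if key not in P0_cache:
            P0_cache[key] = _transition_matrix(Q0[name], dt)
        return P0_cache[key]

    # ---------------- main loop
    t = 0.0
    enz_accum = 0.0
    enz_flux = np.zeros(n)
    _record(0.0)
    for a, b, amp, inj_who, dt_seg in segments:
        seg_len = b - a
        n_steps = max(1, int(round(seg_len / dt_seg)))
        dt = seg_len / n_steps
        # per-segment transition matrices
        if amp is None:
            P_ampa = _P0("ampa", dt)
            P_na = _P0("nmda_a", dt)
            P_nb = _P0("nmda_b", dt)
            P_gaba = _P0("gaba", dt)
        else:
            Qa = np.stack([ch.ampar_Q(g, T, p) for g in amp])
            Qna = np.stack([ch.nmdar_Q(g, T, "GluN2A", p) for g in amp])
            Qnb = np.stack([ch.nmdar_Q(g, T, "GluN2B", p) for g in amp])
            Qg = np.stack([ch.gabar_Q(g, T, p) for g in amp])
            P_ampa = _transition_matrix(Qa, dt)
            P_na = _transition_matrix(Qna, dt)
            P_nb = _transition_matrix(Qnb, dt)
            P_gaba = _transition_matrix(Qg, dt)

        # constant injection for the segment
        inj = np.zeros(n)
        for who in inj_who:
            if who is None:
                inj += p["I_amp"]
            else:
                inj[who] += p["I_amp"]
        use = np.where(inj > 0, p["bap_use_scale"], 0.0)

        for _ in range(n_steps):
            # --- receptor populations (exact per-step transition matrices)
            ampa = _step_population(ampa, P_ampa,
                                    None if det_ampa else rng_chan)
            nmda_a = _step_population(nmda_a, P_na,
                                      None if det_nmda else rng_chan)
            nmda_b = _step_population(nmda_b, P_nb,
                                      None if det_nmda else rng_chan)
            gaba = _step_population(gaba, P_gaba,
                                    None if det_gaba else rng_chan)

            # --- VGCC gates at the current spine voltage
            aTm, bTm = _gate_ab("Tm", v_sp)
            aTh, bTh = _gate_ab("Th", v_sp)
            aRm, bRm = _gate_ab("Rm", v_sp)
            aRh, bRh = _gate_ab("Rh", v_sp)
            g_rng = None if det_vgcc else rng_chan
            mT = _step_two_state_gates(mT, aTm, bTm, dt, g_rng)
            hT = _step_two_state_gates(hT, aTh, bTh, dt, g_rng)
            mR = _step_two_state_gates(mR, aRm, bRm, dt, g_rng)
            hR = _step_two_state_gates(hR, aRh, bRh, dt, g_rng)
            aL = 0.83e3 / (1.0 + np.exp((13.7 - v_sp) / 6.1)) * rho_v.rho_f
            b1L = 0.53e3 / (1.0 + np.exp((v_sp - 11.5) / 6.4)) * rho_v.rho_b
            b2L = 1.86e3 / (1.0 + np.exp((v_sp - 18.8) / 6.17)) * rho_v.rho_b
            if det_vgcc:
                esc_c = -np.expm1(-2 * aL * dt)
                esc_1 = -np.expm1(-b1L * dt)
                esc_2 = -np.expm1(-b2L * dt)
                moved = vgcc_l[:, 0] * esc_c
                back1 = vgcc_l[:, 1] * esc_1
                back2 = vgcc_l[:, 2] * esc_2
                vgcc_l = vgcc_l + np.stack(
                    [-moved + back1 + back2,
                     0.5 * moved - back1, 0.5 * moved - back2], axis=1)
            else:
                moved = rng_chan.binomial(vgcc_l[:, 0], -np.expm1(-2 * aL * dt))
                to1 = rng_chan.binomial(moved, 0.5)
                back1 = rng_chan.binomial(vgcc_l[:, 1], -np.expm1(-b1L * dt))
                back2 = rng_chan.binomial(vgcc_l[:, 2], -np.expm1(-b2L * dt))
                vgcc_l = vgcc_l + np.stack(
                    [-moved + back1 + back2, to1 - back1,
                     (moved - to1) - back2], axis=1)

            # --- conductances and calcium currents
            g_ampa = ch.ampar_conductance(ampa, p)
            open_nmda = (nmda_a[:, 5] + nmda_a[:, 6]
                         + nmda_b[:, 5] + nmda_b[:, 6])
            B = ch.mg_block(v_sp, cond.mg_o, p)
            g_nmda = open_nmda * B * g_nmda_unit
            g_gaba = (gaba[:, 3] + gaba[:, 4]) * p["gamma_GABA"]
            g_sk = p["gamma_SK"] * p["N_SK"] * msk
            drive = ghk_drive(v_sp, ca, cond.ca_o, T, p)
            if det_vgcc:
                o_T = n_vgcc * mT * hT
                o_R = n_vgcc * mR * hR
            else:
                o_T = (mT & hT).sum(axis=1)
                o_R = (mR & hR).sum(axis=1)
            i_t = p["gamma_CaT"] * o_T * drive
            i_r = p["gamma_CaR"] * o_R * drive
            i_l = p["gamma_CaL"] * (vgcc_l[:, 1] + vgcc_l[:, 2]) * drive
            i_ca_nmda = p["f_Ca_NMDA"] * g_nmda * drive
            i_ca_total = i_ca_nmda + i_t + i_r + i_l

            # --- enzymes (RK2 on a ~0.25 ms sub-grid; calcium frozen over it;
            #     substeps shrink with calcium since lumped rates grow ~ Ca²)
            enz_accum += dt
            if enz_accum >= 2.5e-4 - 1e-12:
                ca_max = float(ca.max())
                rate_max = max(
                    500.0,
                    20000.0 / (2000.0 + 200.0 * ca_max) * ca_max * ca_max,
                    5776.0 / (300.0 + 76.0 * ca_max) * ca_max * ca_max,
                )
                m_sub = max(1, int(np.ceil(enz_accum * rate_max / 0.4)))
                h = enz_accum / m_sub
                for _e in range(m_sub):
                    dE1, _ = enzyme_derivatives(E, ca, T, p, with_ca_flux=True)
                    dE2, enz_flux = enzyme_derivatives(
                        E + 0.5 * h * dE1, ca, T, p, with_ca_flux=True)
                    E = E + h * dE2
                    np.clip(E, 0.0, None, out=E)
                enz_accum = 0.0

            # --- calcium + buffers (exponential-Euler substeps; a single
            #     stable update suffices near the resting equilibrium)
            if float(np.abs(i_ca_total).max()) < 1e-3 and \
                    float(np.abs(ca - p["Ca_infty"]).max()) < 0.02:
                n_sub = 1
            else:
                n_sub = max(1, int(round(dt / 5e-5)))
            dts = dt / n_sub
            for _s in range(n_sub):
                b_free = p["buff_con"] - buff
                lam_ca = (1.0 / p["tau_Ca"] + 1.0 / tau_diff
                          + p["kon_buff"] * b_free)
                src = (p["Ca_infty"] / p["tau_Ca"]
                       + np.maximum(p["Ca_infty"], ca / 3.0) / tau_diff
                       + i_ca_total * conv_ca
                       + p["koff_buff"] * buff + enz_flux)
                if cond.dye_mode:
                    d_free = p["dye_con"] - dye
                    lam_ca = lam_ca + p["kon_dye"] * d_free
                    src = src + p["koff_dye"] * dye
                    lam_d = p["kon_dye"] * ca + p["koff_dye"]
                    dye = (p["kon_dye"] * p["dye_con"] * ca / lam_d
                           + (dye - p["kon_dye"] * p["dye_con"] * ca / lam_d)
                           * np.exp(-lam_d * dts))
                ca_inf_loc = src / lam_ca
                ca = ca_inf_loc + (ca - ca_inf_loc) * np.exp(-lam_ca * dts)
                np.clip(ca, 0.0, None, out=ca)
                lam_b = p["kon_buff"] * ca + p["koff_buff"]
                b_inf = p["kon_buff"] * p["buff_con"] * ca / lam_b
                buff = b_inf + (buff - b_inf) * np.exp(-lam_b * dts)

            # --- SK activation (exponential Euler)
            tau_sk = p["tau_SK"] * rho_sk.rho_b
            m_inf_sk = ch.sk_activation(ca, p) * rho_sk.rho_f * tau_sk
            msk = m_inf_sk + (msk - m_inf_sk) * np.exp(-dt / tau_sk)

            # --- soma gates
            am, bm, ah, bh, n_inf, n_tau = soma_gate_rates(v_soma)
            gm = am / (am + bm) + (gm - am / (am + bm)) * np.exp(-(am + bm) * dt)
            gh = ah / (ah + bh) + (gh - ah / (ah + bh)) * np.exp(-(ah + bh) * dt)
            gn = n_inf + (gn - n_inf) * np.exp(-dt / n_tau)

            # --- attenuation resources
            dlam, daux, dage = adaptation_derivatives(lam, lam_aux, lam_age,
                                                      use, cond)
            lam = np.clip(lam + dt * dlam, 1e-4, 1.0)
            lam_aux = np.clip(lam_aux + dt * daux, 1e-4, 1.0)
            lam_age = np.clip(lam_age + dt * dage, 1e-4, 1.0)

            # --- voltages (exponential Euler, semi-implicit in conductance)
            g_ad = lam * p["g_diff"] * phi_d
            g_tot_sp = p["g_neck"] + p["gL_sp"] + g_ampa + g_nmda + g_sk
            src_sp = (p["g_neck"] * v_dend + p["gL_sp"] * EL
                      + g_sk * p["Erev_SK"] + i_ca_total)
            v_inf = src_sp / g_tot_sp
            v_sp = v_inf + (v_sp - v_inf) * np.exp(-g_tot_sp / p["C_sp"] * 1e3 * dt)

            g_tot_d = g_ad + p["g_neck"] + p["gL_dend"] + g_gaba
            src_d = (g_ad * v_soma + p["g_neck"] * v_sp + p["gL_dend"] * EL
                     + g_gaba * erev_cl)
            v_inf = src_d / g_tot_d
            v_dend = v_inf + (v_dend - v_inf) * np.exp(
                -g_tot_d / p["C_dend"] * 1e3 * dt)

            g_na = lam_age * p["gamma_Na"] * gm ** 3 * gh
            g_k = p["gamma_K"] * gn
            g_tot_s = g_ad + p["gL_soma"] + g_na + g_k
            src_s = (g_ad * v_dend + p["gL_soma"] * EL + g_na * p["Erev_Na"]
                     + g_k * p["Erev_K"] + lam_age * inj)
            v_inf = src_s / g_tot_s
            v_soma = v_inf + (v_soma - v_inf) * np.exp(
                -g_tot_s / p["C_soma"] * 1e3 * dt)

            if cfg.check_conservation:
                assert int(np.abs(ampa.sum(axis=1) - p["N_AMPA"]).max()) == 0
                assert np.array_equal(nmda_a.sum(axis=1), counts_2a)
                assert np.array_equal(nmda_b.sum(axis=1), counts_2b)
                assert int(np.abs(gaba.sum(axis=1) - p["N_GABA"]).max()) == 0
                assert int(np.abs(vgcc_l.sum(axis=1) - n_vgcc).max()) == 0
                tot = E[:, [0, 1, 2, 3, 5, 6, 7, 8, 9, 10, 11, 12, 16]].sum(axis=1)
                assert np.abs(tot - p["CaM_con"]).max() < 1e-6
                kin = E[:, 4:15].sum(axis=1)
                assert np.abs(kin - p["mKCaM_con"]).max() < 1e-6
                assert np.abs(E[:, 15] + E[:, 16] - p["mCaN_con"]).max() < 1e-6
            t += dt
            _record(t)

    if enz_accum > 0.0:
        ca_max = float(ca.max())
        rate_max = max(500.0,
                       20000.0 / (2000.0 + 200.0 * ca_max) * ca_max * ca_max,
                       5776.0 / (300.0 + 76.0 * ca_max) * ca_max * ca_max)
        m_sub = max(1, int(np.ceil(enz_accum * rate_max / 0.4)))
        h = enz_accum / m_sub
        for _e in range(m_sub):
            dE1, _ = enzyme_derivatives(E, ca, T, p, with_ca_flux=True)
            dE2, _ = enzyme_derivatives(E + 0.5 * h * dE1, ca, T, p,
                                        with_ca_flux=True)
            E = np.clip(E + h * dE2, 0.0, None)

    # ---------------- enzyme-only tail to the readout horizon
    if t_end > t_main + 1e-9 and i_ro < t_ro.size:
        ca_rest = ca.copy()
        y0 = E.reshape(-1)

        def rhs(_, y):
            return enzyme_derivatives(y.reshape(n, -1), ca_rest, T, p).reshape(-1)

        t_eval = t_ro[i_ro:]
        sol = solve_ivp(rhs, (t, t_ro[-1]), y0, t_eval=t_eval, method="LSODA",
                        rtol=1e-7, atol=1e-9)
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"enzyme tail integration failed: {sol.message}")
        Y = sol.y.T.reshape(t_eval.size, n, -1)
        c_act, k_act = active_pair(Y)
        can_tr[i_ro:] = c_act
        kii_tr[i_ro:] = k_act
        cam_tr[i_ro:] = Y[..., 1] + Y[..., 2] + Y[..., 3]
        E = Y[-1]
        i_ro = t_ro.size

    # ---------------- geometric readout over the recorded enzyme orbits
    weights, act_p, act_d, chain = ro.run_readout(
        t_ro, can_tr.T, kii_tr.T, rng=rng_chain, params=p)

    rec_out = {k: v.T for k, v in rec.items()}
    rec_out["cam_bound"] = cam_tr.T
    return SimulationResult(
        t=t_out, records=rec_out,
        t_readout=t_ro, can=can_tr.T, camkii=kii_tr.T,
        weights=weights, act_p=act_p, act_d=act_d, chain=chain,
        presyn=presyn, protocol=protocol, conditions=cond, config=cfg,
    )


def batch_run(
    protocol: Protocol | Sequence[Protocol],
    conditions: ExperimentalConditions | None = None,
    n_samples: int = 100,
    seed: int = 0,
    **config_kwargs,
) -> SimulationResult:
    """Run ``n_samples`` independent samples and summarise the outcomes.

    A single shared :class:`Protocol` is simulated vectorised; a sequence of
    per-sample protocols (e.g. independent jitter realisations) is simulated
    sample by sample with per-sample child seeds and the results concatenated.
    """
    if isinstance(protocol, Protocol):
        cfg = RunConfig(seed=seed, n_samples=n_samples, **config_kwargs)
        return simulate(protocol, conditions, cfg)

    protos = list(protocol)
    seeds = np.random.SeedSequence(seed).spawn(len(protos))
    results = [
        simulate(pr, conditions,
                 RunConfig(seed=int(s.generate_state(1)[0] % (2 ** 31)),
                           n_samples=1, **config_kwargs))
        for pr, s in zip(protos, seeds)
    ]
    first = results[0]
    # per-sample protocols can differ in duration; crop to the common grid
    n_t = min(r.t.size for r in results)
    n_ro = min(r.t_readout.size for r in results)
    return SimulationResult(
        t=first.t[:n_t],
        records={k: np.concatenate([r.records[k][:, :n_t] for r in results])
                 for k in first.records},
        t_readout=first.t_readout[:n_ro],
        can=np.concatenate([r.can[:, :n_ro] for r in results]),
        camkii=np.concatenate([r.camkii[:, :n_ro] for r in results]),
        weights=np.concatenate([r.weights for r in results]),
        act_p=np.concatenate([r.act_p for r in results]),
        act_d=np.concatenate([r.act_d for r in results]),
        chain=ro.PlasticityChain(
            ltd=np.concatenate([r.chain.ltd for r in results]),
            nc=np.concatenate([r.chain.nc for r in results]),
            ltp=np.concatenate([r.chain.ltp for r in results]),
        ),
        presyn=[tr for r in results for tr in r.presyn],
        protocol=protos[0], conditions=first.conditions, config=first.config,
    )
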