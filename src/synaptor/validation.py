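"""Reproduction of published observables of the synapse model.

Each function recomputes, from scratch, one quantitative observable that the
experimental/modelling literature reports for this system: the initial
release probability at 2.5 mM extracellular calcium, the use-dependent BaP
attenuation over a 5 Hz train, receptor deactivation time constants,
post-stimulus enzyme decay time constants, and the single-EPSP calcium
transient amplitude.  They are used by ``scripts/acceptance.py`` and by the
acceptance test suite.

Problem sizes (sample counts, relaxation horizons) are chosen as the smallest
that give stable sample means for these observables; they are stated per
function.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .analysis import fit_decay
from .channels import (AMPA_OPEN, GABA_OPEN, NMDA_OPEN, ampar_Q, gabar_Q,
                       nmdar_Q, occupancy_decay_tau)
from .conditions import ExperimentalConditions
from .electrical import simulate_electrical
from .engine import RunConfig, simulate
from .presynapse import release_probability
from .protocols import build_protocol, preset_conditions

__all__ = [
    "initial_release_probability", "bap_attenuation_30th",
    "receptor_decay_ms", "tigaret_enzyme_decays", "fujii_can_decay",
    "single_epsp_calcium_peak",
]


def initial_release_probability(ca_o: float = 2.5) -> float:
    """Release probability (%) of the first spike from rest.

    From rest the presynaptic calcium resource jumps to exactly 1 on the
    first spike (the jump size starts at 1), so this is the release sigmoid
    evaluated at Ca_pre = 1 with a full docked pool.
    """
    return 100.0 * release_probability(1.0, ca_o, docked=25)


def bap_attenuation_30th(conditions: ExperimentalConditions | None = None) -> float:
    """Dendritic BaP amplitude at pulse 30 of a 5 Hz train, % of pulse 1.

    Deterministic electrical-subsystem run (the attenuation resources and
    compartment voltages carry no intrinsic noise).
    """
    cond = conditions or ExperimentalConditions()
    post = np.arange(30) / 5.0
    trace = simulate_electrical(post, cond, t_end=post[-1] + 0.15)
    peaks = trace.pulse_peaks(post, "v_dend")
    return 100.0 * float(peaks[29] / peaks[0])


def receptor_decay_ms(receptor: str, T: float = 35.0) -> float:
    """Deactivation time constant (ms) after a standard 1 ms, 1 mM pulse.

    Deterministic occupancy propagation of the receptor Markov chain followed
    by a single-exponential fit of the open-probability decay.
    ``receptor`` ∈ {"ampa", "glun2a", "glun2b", "gaba"}.
    """
    r = receptor.lower()
    if r == "ampa":
        tau, _, _ = occupancy_decay_tau(ampar_Q(1000.0, T), ampar_Q(0.0, T),
                                        AMPA_OPEN, horizon=0.02, dt=1e-6)
    elif r in ("glun2a", "glun2b"):
        sub = "GluN2A" if r == "glun2a" else "GluN2B"
        tau, _, _ = occupancy_decay_tau(nmdar_Q(1000.0, T, sub),
                                        nmdar_Q(0.0, T, sub),
                                        NMDA_OPEN, horizon=2.0, dt=1e-4)
    elif r == "gaba":
        tau, _, _ = occupancy_decay_tau(gabar_Q(1000.0, T), gabar_Q(0.0, T),
                                        GABA_OPEN, horizon=0.2, dt=1e-5)
    else:
        raise ValueError(f"unknown receptor {receptor!r}")
    return tau * 1e3


def _fit_tail(t: np.ndarray, y: np.ndarray, start: float,
              frac: float = 0.05) -> float:
    """Single-exponential decay constant of a post-stimulus trace.

    The fit runs from the post-``start`` peak down to where the trace first
    reaches ``frac`` of its peak above baseline (baseline = trace end), so the
    extracted constant describes the dominant decay rather than depending on
    an arbitrary window length.
    """
    m = t >= start
    tt, yy = t[m] - start, y[m]
    base = float(np.mean(yy[-max(3, yy.size // 20):]))
    i_pk = int(np.argmax(yy))
    amp = yy[i_pk] - base
    below = np.nonzero(yy[i_pk:] - base < frac * amp)[0]
    i_end = i_pk + (below[0] if below.size else yy.size - i_pk)
    i_end = max(i_end, i_pk + 10)
    tau, _ = fit_decay(tt[: i_end], yy[: i_end], baseline=base)
    return tau


def tigaret_enzyme_decays(seed: int = 0, n_samples: int = 20) -> Dict[str, float]:
    """Post-stimulus enzyme decay constants after 30 pairings at 5 Hz.

    Simulates ``1Pre1Post10, 30 at 5 Hz`` under the default adult conditions,
    averages the enzyme activity traces over samples and fits single
    exponentials to the post-stimulus decays.  Returns
    ``{"cam_ms": ..., "camkii_s": ..., "can_s": ...}``.
    """
    proto = build_protocol("1Pre1Post10, 30 at 5 Hz")
    res = simulate(proto, ExperimentalConditions(),
                   RunConfig(seed=seed, n_samples=n_samples, tail=500.0,
                             record_channels=False))
    t = res.t_readout
    end = proto.duration + 0.2
    return {
        "cam_ms": _fit_tail(t, res.records["cam_bound"].mean(axis=0), end) * 1e3,
        "camkii_s": _fit_tail(t, res.camkii.mean(axis=0), end),
        "can_s": _fit_tail(t, res.can.mean(axis=0), end),
    }


def fujii_can_decay(temperature: float = 25.0, seed: int = 0,
                    n_samples: int = 20) -> float:
    """CaN decay constant (s) after a 100-pulse 20 Hz uncaging train.

    Glutamate-uncaging conditions: release failures disabled, 2 mM
    extracellular calcium, magnesium-free, immature tissue; no postsynaptic
    stimulation.  The active-CaN sample mean is fitted with a single
    exponential after the train.
    """
    preset = "fujii2013_25c" if temperature < 30 else "fujii2013_35c"
    cond = preset_conditions(preset, temperature=temperature)
    proto = build_protocol("1Pre, 100 at 20 Hz")
    res = simulate(proto, cond,
                   RunConfig(seed=seed, n_samples=n_samples, tail=320.0,
                             record_channels=False))
    return _fit_tail(res.t_readout, res.can.mean(axis=0), proto.duration + 0.1)


def single_epsp_calcium_peak(seed: int = 0, n_samples: int = 50) -> float:
    """Mean peak free spine calcium (µM) for one successful vesicle release.

    Single presynaptic spike with release forced to succeed, no postsynaptic
    BaP, default conditions; the per-sample peak of the free-calcium trace is
    averaged over samples.
    """
    cond = ExperimentalConditions(forced_release=True)
    proto = build_protocol("1Pre")
    res = simulate(proto, cond,
                   RunConfig(seed=seed, n_samples=n_samples, t_end=1.0,
                             record_channels=False))
    return float(res.records["ca"].max(axis=1).mean())
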