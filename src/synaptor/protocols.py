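"""Stimulation protocol construction.

Protocols are plain lists of presynaptic and postsynaptic spike times built
from the compact naming convention used throughout the STDP/FDP literature,
e.g. ``"1Pre2Post10, 300 at 5 Hz"`` (one presynaptic spike followed 10 ms
later by a postsynaptic doublet, the pairing repeated 300 times at 5 Hz) or
``"2Pre50, 900 at 3 Hz"`` (presynaptic doublets with 50 ms interval at 3 Hz).
Theta-burst stimulation uses the nested form
``"4Pre at 100 Hz repeated 10 times at 5 Hz given in 6 epochs at 0.1 Hz"``.

In-vivo-like variability is modelled by jittering spike times with Gaussian
noise, random spike deletion (sparsity), or independent Poisson trains.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict

import numpy as np

__all__ = [
    "Protocol", "ProtocolError", "build_protocol",
    "apply_jitter", "apply_sparsity", "poisson_protocol",
    "PRESETS", "preset_conditions",
]

#: default interval within a postsynaptic (or presynaptic) doublet/burst when
#: the protocol name does not state one, s
DEFAULT_DOUBLET_ISI = 0.010


class ProtocolError(ValueError):
    """Malformed protocol specification string."""


@dataclass(frozen=True)
class Protocol:
    """Pre- and postsynaptic spike times (s, sorted) plus metadata."""

    pre_times: np.ndarray
    post_times: np.ndarray
    name: str = ""
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self):
        for attr in ("pre_times", "post_times"):
            t = np.asarray(getattr(self, attr), dtype=float)
            if t.size and (not np.all(np.isfinite(t)) or np.any(t < 0)):
                raise ProtocolError(f"{attr} must be finite and non-negative")
            if t.size and np.any(np.diff(t) < 0):
                raise ProtocolError(f"{attr} must be sorted")
            object.__setattr__(self, attr, t)

    @property
    def duration(self) -> float:
        """Time of the last spike (s); 0.0 for an empty protocol."""
        times = [t[-1] for t in (self.pre_times, self.post_times) if t.size]
        return max(times) if times else 0.0

    def shifted(self, offset: float) -> "Protocol":
        return replace(
            self,
            pre_times=self.pre_times + offset,
            post_times=self.post_times + offset,
        )


# the trailing number of a group must not swallow the count of the next group
_GROUP = re.compile(
    r"(\d+)\s*(Pre|Post)\s*(\d+(?:\.\d+)?(?!\d*\s*(?:Pre|Post)))?",
    re.IGNORECASE)
_REP = re.compile(
    r",\s*(\d+)\s*(?:at|@)\s*(\d+(?:\.\d+)?)\s*Hz\s*$", re.IGNORECASE)
_TBS = re.compile(
    r"^\s*(\d+)\s*Pre\s+at\s+(\d+(?:\.\d+)?)\s*Hz\s+repeated\s+(\d+)\s+times?"
    r"\s+at\s+(\d+(?:\.\d+)?)\s*Hz\s+given\s+in\s+(\d+)\s+epochs?\s+at\s+"
    r"(\d+(?:\.\d+)?)\s*Hz\s*$",
    re.IGNORECASE,
)


def _burst(n: int, isi: float) -> np.ndarray:
    return np.arange(n) * isi


def build_protocol(
    spec: str,
    doublet_isi: float = DEFAULT_DOUBLET_ISI,
) -> Protocol:
    """Build a :class:`Protocol` from a protocol-grammar string.

    Grammar (times in ms inside the name, seconds in the output):

    * ``"<a>Pre<b>Post<d>, N at f Hz"`` — a presynaptic spikes then, ``d`` ms
      after the last of them, b postsynaptic spikes; N pairings at f Hz.
      ``"<a>Post<b>Pre<d>, ..."`` is the anticausal variant (delay measured
      from the last postsynaptic spike to the presynaptic one).
    * ``"<a>Pre<isi>, N at f Hz"`` — single-train protocol; a number attached
      to a lone group is the intra-burst interval (ms).
    * ``"<n>Pre at f1 Hz repeated m times at f2 Hz given in k epochs at
      f3 Hz"`` — theta-burst nesting.

    A burst inside a two-group pairing uses ``doublet_isi`` (s) as its
    intra-burst interval unless the group carries its own number in a
    single-group spec.
    """
    text = spec.strip()
    m = _TBS.match(text)
    if m:
        n, f1, reps, f2, epochs, f3 = m.groups()
        n, reps, epochs = int(n), int(reps), int(epochs)
        f1, f2, f3 = float(f1), float(f2), float(f3)
        burst = _burst(n, 1.0 / f1)
        train = np.concatenate([burst + r / f2 for r in range(reps)])
        pre = np.concatenate([train + e / f3 for e in range(epochs)])
        return Protocol(
            np.sort(pre), np.array([]), name=spec,
            metadata={"kind": "tbs", "pulses": n * reps * epochs},
        )

    rep = _REP.search(text)
    if rep:
        n_rep, freq = int(rep.group(1)), float(rep.group(2))
        body = text[: rep.start()]
    else:
        n_rep, freq = 1, 1.0
        body = text

    groups = list(_GROUP.finditer(body))
    if not groups or _GROUP.sub("", body).strip():
        raise ProtocolError(
            f"cannot parse protocol {spec!r} "
            f"(unrecognised text at position {len(_GROUP.sub('', body))})")
    if len(groups) > 2:
        raise ProtocolError(f"at most two spike groups allowed: {spec!r}")

    pre_unit: list[np.ndarray] = []
    post_unit: list[np.ndarray] = []
    if len(groups) == 1:
        count, kind, num = groups[0].groups()
        count = int(count)
        isi = float(num) * 1e-3 if num else doublet_isi
        (pre_unit if kind.lower() == "pre" else post_unit).append(
            _burst(count, isi))
    else:
        (c1, k1, num1), (c2, k2, num2) = (g.groups() for g in groups)
        c1, c2 = int(c1), int(c2)
        if k1.lower() == k2.lower():
            raise ProtocolError(f"pairing needs one Pre and one Post group: {spec!r}")
        isi1 = float(num1) * 1e-3 if num1 else doublet_isi
        delay = float(num2) * 1e-3 if num2 else 0.0
        g1 = _burst(c1, isi1)
        g2 = _burst(c2, doublet_isi) + (g1[-1] if g1.size else 0.0) + delay
        (pre_unit if k1.lower() == "pre" else post_unit).append(g1)
        (pre_unit if k2.lower() == "pre" else post_unit).append(g2)

    onsets = np.arange(n_rep) / freq
    pre = (np.sort(np.concatenate([u + t0 for t0 in onsets for u in pre_unit]))
           if pre_unit else np.array([]))
    post = (np.sort(np.concatenate([u + t0 for t0 in onsets for u in post_unit]))
            if post_unit else np.array([]))
    return Protocol(
        pre, post, name=spec,
        metadata={"kind": "pairing", "repetitions": n_rep, "frequency": freq},
    )


def apply_jitter(protocol: Protocol, sigma: float, rng: np.random.Generator) -> Protocol:
    """Perturb every spike time with independent N(0, sigma²) noise (sigma s).

    Output trains are re-sorted; times jittered below zero are clamped at 0.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return protocol

    def jit(t: np.ndarray) -> np.ndarray:
        return np.sort(np.clip(t + rng.normal(0.0, sigma, t.size), 0.0, None))

    return Protocol(
        jit(protocol.pre_times), jit(protocol.post_times),
        name=f"{protocol.name} + jitter {sigma * 1e3:g} ms",
        metadata={**protocol.metadata, "jitter_s": sigma},
    )


def apply_sparsity(protocol: Protocol, p_remove: float,
                   rng: np.random.Generator) -> Protocol:
    """Delete each spike independently with probability ``p_remove``."""
    if not 0.0 <= p_remove <= 1.0:
        raise ValueError("p_remove must be in [0, 1]")

    def thin(t: np.ndarray) -> np.ndarray:
        return t[rng.random(t.size) >= p_remove]

    return Protocol(
        thin(protocol.pre_times), thin(protocol.post_times),
        name=f"{protocol.name} - {p_remove:.0%} removed",
        metadata={**protocol.metadata, "sparsity": p_remove},
    )


def poisson_protocol(rate_pre: float, rate_post: float, duration: float,
                     rng: np.random.Generator) -> Protocol:
    """Two independent homogeneous Poisson spike trains of given rates (Hz)."""
    if rate_pre < 0 or rate_post < 0 or duration < 0:
        raise ValueError("rates and duration must be non-negative")

    def train(rate: float) -> np.ndarray:
        n = rng.poisson(rate * duration)
        return np.sort(rng.uniform(0.0, duration, n))

    return Protocol(
        train(rate_pre), train(rate_post),
        name=f"Poisson {rate_pre:g}/{rate_post:g} Hz, {duration:g} s",
        metadata={"kind": "poisson", "rate_pre": rate_pre,
                  "rate_post": rate_post, "duration": duration},
    )


# ----------------------------------------------------------------------
# named experimental presets: conditions bundle + canonical protocols
# ----------------------------------------------------------------------

#: conditions keyword bundles for the experiment families the model covers.
#: Ages are in postnatal days (organotypic cultures use days in vitro),
#: temperatures in °C, concentrations in mM, distances in µm.
PRESETS: Dict[str, Dict] = {
    # CA3-CA1 STDP with burst requirement (default calibration conditions)
    "tigaret2016": dict(age=50.0, temperature=35.0, ca_o=2.5, mg_o=1.3,
                        d_soma=200.0),
    # frequency-dependent plasticity, adult and young
    "dudekbear1992": dict(age=35.0, temperature=35.0, ca_o=2.5, mg_o=1.5,
                          d_soma=200.0, evoked_ap_enabled=True),
    "dudekbear1993": dict(age=11.0, temperature=35.0, ca_o=2.5, mg_o=1.5,
                          d_soma=200.0, evoked_ap_enabled=True),
    # STDP vs extracellular Ca/Mg
    "inglebert2020": dict(age=15.0, temperature=30.0, ca_o=2.5, mg_o=1.3,
                          d_soma=200.0),
    # low-frequency depression in young animals
    "mizuno2001": dict(age=13.0, temperature=30.0, ca_o=2.4, mg_o=1.2,
                       d_soma=200.0, evoked_ap_enabled=True),
    # age-dependent STDP studies
    "meredith2003": dict(age=11.0, temperature=26.0, ca_o=2.0, mg_o=2.0,
                         d_soma=200.0),
    "wittenberg2006": dict(age=18.0, temperature=25.0, ca_o=2.0, mg_o=1.0,
                           d_soma=200.0),
    # glutamate-uncaging enzyme imaging (no release failures)
    "chang2019_25c": dict(age=7.0, temperature=25.0, ca_o=1.0, mg_o=2.0,
                          d_soma=200.0, forced_release=True),
    "chang2019_35c": dict(age=7.0, temperature=35.0, ca_o=1.0, mg_o=2.0,
                          d_soma=200.0, forced_release=True),
    "fujii2013_25c": dict(age=12.0, temperature=25.0, ca_o=2.0, mg_o=0.0,
                          d_soma=200.0, forced_release=True),
    "fujii2013_35c": dict(age=12.0, temperature=35.0, ca_o=2.0, mg_o=0.0,
                          d_soma=200.0, forced_release=True),
}


def preset_conditions(name: str, **overrides):
    """Instantiate :class:`~synaptor.conditions.ExperimentalConditions` for a
    named experimental preset, with optional keyword overrides."""
    from .conditions import ExperimentalConditions

    try:
        kwargs = dict(PRESETS[name.lower()])
    except KeyError as err:
        raise KeyError(
            f"unknown preset {name!r}; known: {sorted(PRESETS)}") from err
    kwargs.update(overrides)
    return ExperimentalConditions(**kwargs)
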