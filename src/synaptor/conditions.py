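"""Experimental conditions and every condition-dependent scalar of the model.

The model's behaviour is reshaped by the experimental context a slice
physiologist controls: animal age (receptor subunit composition, chloride
reversal, back-propagation strength), bath temperature (kinetic rate scalings
for every receptor class and for the enzymes), the aCSF calcium and magnesium
composition (release probability, NMDAr conductance and block), and the
distance of the synapse from the soma (back-propagating action-potential
attenuation).  All of those dependencies are logistic curves fitted to
published datasets; they are evaluated here, in one place.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import FrozenSet, Tuple

from .params import ParameterSet, default_params

__all__ = [
    "ExperimentalConditions",
    "RateScalingPair",
    "temperature_factors",
    "nmda_subunit_counts",
    "erev_chloride",
    "gamma_nmda",
    "phi_dist",
    "bap_age_step",
]

#: stochastic sources that may individually be switched to mean-field mode
KNOWN_SOURCES = frozenset(
    {"presyn", "ampa", "nmda", "gaba", "vgcc", "plasticity"}
)

TEMPERATURE_VALID_RANGE = (15.0, 45.0)  # °C, fitted validity range


@dataclass(frozen=True)
class RateScalingPair:
    """Forward/backward kinetic rate multipliers for one mechanism."""

    rho_f: float
    rho_b: float

    def __post_init__(self):
        if not (self.rho_f > 0 and self.rho_b > 0):
            raise ValueError("rate scalings must be positive")


@dataclass(frozen=True)
class ExperimentalConditions:
    """The experimental knobs of a simulated plasticity experiment.

    Parameters
    ----------
    age:
        Animal age in days (≥ 0).  Controls the GluN2A:GluN2B split, the
        chloride reversal potential and the BaP attenuation step.
    temperature:
        Bath temperature in °C.  Values outside the fitted 15-45 °C range
        trigger a warning (not an error).
    ca_o, mg_o:
        Extracellular calcium / magnesium, mM (aCSF composition).
    d_soma:
        Distance of the spine from the soma, µm.
    dye_mode:
        Simulate a Fluo-5F calcium-dye experiment (adds the dye species,
        shifts the effective temperature, damps the BaP injection).
    evoked_ap_enabled:
        Allow EPSPs to evoke somatic APs (LFP-style field stimulation).
    forced_release:
        Every presynaptic spike releases transmitter (glutamate-uncaging
        experiments, where failures are absent by construction).
    deterministic_sources:
        Stochastic sources replaced by their mean-field (expected-occupancy)
        dynamics; any subset of ``{"presyn","ampa","nmda","gaba","vgcc",
        "plasticity"}``.
    """

    age: float = 50.0
    temperature: float = 35.0
    ca_o: float = 2.5
    mg_o: float = 1.3
    d_soma: float = 200.0
    dye_mode: bool = False
    evoked_ap_enabled: bool = False
    forced_release: bool = False
    deterministic_sources: FrozenSet[str] = frozenset()
    params: ParameterSet = field(default_factory=default_params)

    def __post_init__(self):
        if self.ca_o <= 0:
            raise ValueError("ca_o must be positive")
        if self.mg_o < 0:
            raise ValueError("mg_o must be non-negative")
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if self.d_soma < 0:
            raise ValueError("d_soma must be non-negative")
        object.__setattr__(
            self, "deterministic_sources", frozenset(self.deterministic_sources)
        )
        unknown = self.deterministic_sources - KNOWN_SOURCES
        if unknown:
            raise ValueError(f"unknown stochastic source(s): {sorted(unknown)}")
        lo, hi = TEMPERATURE_VALID_RANGE
        if not lo <= self.temperature <= hi:
            warnings.warn(
                f"temperature {self.temperature} °C is outside the fitted "
                f"validity range [{lo}, {hi}] °C",
                stacklevel=2,
            )

    def with_(self, **changes) -> "ExperimentalConditions":
        return replace(self, **changes)

    def is_deterministic(self, source: str) -> bool:
        return source in self.deterministic_sources


def temperature_factors(T: float, mechanism: str) -> RateScalingPair:
    """Forward/backward temperature rate multipliers for one mechanism.

    Each factor is a logistic curve in temperature fitted to kinetics
    measurements for that receptor class or enzyme.  Mechanisms for which a
    single factor was fitted (GABA closing rates, CaMKII dissociation rates)
    return 1.0 for the other member of the pair.
    """
    if not math.isfinite(T):
        raise ValueError("temperature must be finite")
    m = mechanism.upper()
    if m == "AMPA":
        rf = 10.273 / (1.0 + math.exp(-0.473 * (T - 31.724)))
        rb = 5.134 / (1.0 + math.exp(-0.367 * (T - 28.976)))
    elif m == "NMDA":
        rf = -1230.680 + 1239.067 / (1.0 + math.exp(-0.099 * (T + 37.631)))
        rb = 3.036 + 1621.616 / (1.0 + math.exp(-0.106 * (T - 98.999)))
    elif m == "GABA":
        # only the closing rates carry a temperature factor
        rf = 1.0
        rb = 1.470 - 1.279 / (1.0 + math.exp(0.191 * (T - 32.167)))
    elif m in ("VGCC", "CAN"):
        # calcineurin shares the VGCC factor pair
        rf = 2.503 - 0.304 / (1.0 + math.exp(1.048 * (T - 30.668)))
        rb = 0.729 + 3.225 / (1.0 + math.exp(-0.330 * (T - 36.279)))
    elif m == "SK":
        rf = 0.005 + 2.205 / (1.0 + math.exp(-0.334 * (T - 25.59)))
        rb = 149.37 - 147.61 / (1.0 + math.exp(0.093 * (T - 98.85)))
    elif m == "CAMKII":
        # only the dissociation rates k2, k3, k5 carry a temperature factor
        rf = 1.0
        rb = 162.171 - 161.426 / (1.0 + math.exp(0.511 * (T - 45.475)))
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    return RateScalingPair(rf, rb)


def _round_half_away(x: float) -> int:
    """round() with half-away-from-zero ties (the convention used for counts)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def nmda_subunit_counts(
    age: float, noise: float = 0.0, n_nmda: int = 15
) -> Tuple[int, int]:
    """Split the NMDAr population into (GluN2A, GluN2B) counts by age.

    The GluN2B:GluN2A expression ratio decays with developmental age along a
    logistic fitted to mouse hippocampus data; an optional standard-normal
    ``noise`` draw (scaled by 0.05) lets ~1 receptor flip subtype between
    samples.  Counts are obtained by independent rounding of the two shares.
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    z = min(0.099 * (age - 25.102), 700.0)
    r = 0.507 + 0.964 / (1.0 + math.exp(z)) + 0.05 * noise
    r = max(r, 0.0)
    n_2b = _round_half_away(n_nmda * r / (r + 1.0))
    n_2a = _round_half_away(n_nmda / (r + 1.0))
    return n_2a, n_2b


def erev_chloride(age: float) -> float:
    """Chloride reversal potential (mV) as a function of age in days.

    Immature neurons have depolarising GABA currents (Erev above rest); the
    KCC2-driven maturation shifts Erev towards the adult -92.6 mV asymptote.
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    return -92.649 + 243.515 / (1.0 + math.exp(min(0.091 * (age - 0.691), 700.0)))


def gamma_nmda(ca_o: float) -> float:
    """NMDAr single-channel conductance (pS) vs extracellular calcium (mM)."""
    if ca_o <= 0:
        raise ValueError("ca_o must be positive")
    return 33.949 + 58.388 / (1.0 + math.exp(min(4.0 * (ca_o - 2.701), 700.0)))


def phi_dist(d_soma: float) -> float:
    """Distance attenuation factor on the dendritic axial conductance."""
    if d_soma < 0:
        raise ValueError("d_soma must be non-negative")
    return 0.1 + 1.4 / (1.0 + math.exp(min(0.02 * (d_soma - 230.3), 700.0)))


def bap_age_step(age: float) -> float:
    """Age-dependent BaP attenuation step factor (per use of the resource)."""
    if age < 0:
        raise ValueError("age must be non-negative")
    return 1.391e-4 / (1.0 + math.exp(min(0.135 * (age - 16.482), 700.0)))
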