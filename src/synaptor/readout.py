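"""Geometric plasticity readout.

The joint trajectory of active calcineurin (CaN, x-axis) and active CaMKII
(y-axis) is classified against two fixed polygonal regions of the activity
plane, fitted once to a corpus of plasticity experiments: a rectangular LTP
region and an adjoining LTD region.  Time spent inside a region charges a
leaky activation variable (linear rise inside, exponential decay outside);
the activations drive sigmoidal transition rates of a population of 100
processes hopping between LTD, no-change (NC) and LTP states.  The readout's
output is the percent weight change LTP − LTD.

Boundary points count as inside (the polygons are closed); the published LTD
vertex list is unordered and is canonicalised here by angular sort about the
centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import shapely
from shapely.geometry import Polygon

from .params import LTD_VERTICES, LTP_VERTICES, ParameterSet, default_params

__all__ = [
    "PlasticityRegions", "default_regions", "region_indicator",
    "activation_step", "plasticity_rates", "PlasticityChain",
    "chain_step_probabilities", "weight_change", "run_readout",
]


def _canonical_polygon(vertices) -> Polygon:
    """Order vertices by angle about their centroid and build a simple polygon."""
    pts = np.asarray(vertices, dtype=float)
    c = pts.mean(axis=0)
    order = np.argsort(np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0]))
    poly = Polygon(pts[order])
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("plasticity region vertices do not form a simple polygon")
    return poly


@dataclass(frozen=True)
class PlasticityRegions:
    """The LTP and LTD polygons in the (CaN µM, CaMKII µM) plane."""

    ltp: Polygon = field(default_factory=lambda: _canonical_polygon(LTP_VERTICES))
    ltd: Polygon = field(default_factory=lambda: _canonical_polygon(LTD_VERTICES))

    def indicators(self, can, camkii) -> Tuple[np.ndarray, np.ndarray]:
        """Vectorised membership (boundary-inclusive) of points in each region."""
        can = np.asarray(can, dtype=float)
        camkii = np.asarray(camkii, dtype=float)
        in_ltp = shapely.intersects_xy(self.ltp, can, camkii)
        in_ltd = shapely.intersects_xy(self.ltd, can, camkii)
        return in_ltp, in_ltd


_DEFAULT_REGIONS = None


def default_regions() -> PlasticityRegions:
    global _DEFAULT_REGIONS
    if _DEFAULT_REGIONS is None:
        _DEFAULT_REGIONS = PlasticityRegions()
    return _DEFAULT_REGIONS


def region_indicator(can, camkii,
                     regions: PlasticityRegions | None = None):
    """(1_LTP, 1_LTD) indicators for points of the activity plane."""
    regions = regions or default_regions()
    in_p, in_d = regions.indicators(can, camkii)
    return in_p.astype(int), in_d.astype(int)


def activation_step(act, inside, a_rate: float, b_rate: float, dt: float):
    """Advance one leaky activation variable over a step of length ``dt``.

    Inside its region the activation rises linearly at ``a_rate``; outside it
    decays exponentially at ``b_rate`` (exact per-step update).
    """
    act = np.asarray(act, dtype=float)
    inside = np.asarray(inside, dtype=bool)
    return np.where(inside, act + a_rate * dt, act * np.exp(-b_rate * dt))


def plasticity_rates(act_p, act_d, params: ParameterSet | None = None):
    """(P_rate, D_rate) in s⁻¹ — sigmoids of the activation variables."""
    p = params or default_params()
    ap = np.asarray(act_p, dtype=float)
    ad = np.asarray(act_d, dtype=float)
    p_rate = (ap * ap) / (ap * ap + p["K_P"] ** 2) / p["t_P"]
    d_rate = (ad * ad) / (ad * ad + p["K_D"] ** 2) / p["t_D"]
    return p_rate, d_rate


@dataclass
class PlasticityChain:
    """Counts of the 100 processes in (LTD, NC, LTP)."""

    ltd: np.ndarray
    nc: np.ndarray
    ltp: np.ndarray

    @classmethod
    def initial(cls, n_samples: int = 1, n_processes: int = 100):
        return cls(
            ltd=np.zeros(n_samples, dtype=np.int64),
            nc=np.full(n_samples, n_processes, dtype=np.int64),
            ltp=np.zeros(n_samples, dtype=np.int64),
        )

    @property
    def total(self) -> np.ndarray:
        return self.ltd + self.nc + self.ltp


def chain_step_probabilities(p_rate, d_rate, dt: float):
    """Exact per-process transition probabilities over a step of length dt.

    Each process moves toward LTP at ``p_rate`` and toward LTD at ``d_rate``
    (LTD ⇄ NC ⇄ LTP topology: the same two rates govern every toward-LTP and
    toward-LTD transition).  For the NC pool the two competing exits share the
    exponential escape probability proportionally to their rates.
    """
    p_rate = np.asarray(p_rate, dtype=float)
    d_rate = np.asarray(d_rate, dtype=float)
    tot = p_rate + d_rate
    esc = -np.expm1(-tot * dt)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_p = np.where(tot > 0, p_rate / np.where(tot > 0, tot, 1.0), 0.0)
    p_nc_to_ltp = esc * frac_p
    p_nc_to_ltd = esc * (1.0 - frac_p)
    p_ltd_to_nc = -np.expm1(-p_rate * dt)
    p_ltp_to_nc = -np.expm1(-d_rate * dt)
    return p_nc_to_ltp, p_nc_to_ltd, p_ltd_to_nc, p_ltp_to_nc


def step_chain(chain: PlasticityChain, p_rate, d_rate, dt: float,
               rng: np.random.Generator | None = None) -> None:
    """Advance the plasticity chain in place over one step.

    With ``rng=None`` the update is mean-field (expected counts) — used when
    the chain is in the deterministic-source set.
    """
    a, b, c, d = chain_step_probabilities(p_rate, d_rate, dt)
    if rng is None:
        to_ltp = chain.nc * a
        to_ltd = chain.nc * b
        ltd_back = chain.ltd * c
        ltp_back = chain.ltp * d
    else:
        esc = np.asarray(a + b)
        moved = rng.binomial(chain.nc, np.clip(esc, 0.0, 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(esc > 0, a / np.where(esc > 0, esc, 1.0), 0.0)
        to_ltp = rng.binomial(moved, np.clip(frac, 0.0, 1.0))
        to_ltd = moved - to_ltp
        ltd_back = rng.binomial(chain.ltd, np.clip(c, 0.0, 1.0))
        ltp_back = rng.binomial(chain.ltp, np.clip(d, 0.0, 1.0))
    chain.nc = chain.nc - to_ltp - to_ltd + ltd_back + ltp_back
    chain.ltd = chain.ltd - ltd_back + to_ltd
    chain.ltp = chain.ltp - ltp_back + to_ltp


def weight_change(chain: PlasticityChain):
    """Predicted synaptic weight change in percent: LTP − LTD counts."""
    return (chain.ltp - chain.ltd).astype(float)


def run_readout(
    t: np.ndarray,
    can: np.ndarray,
    camkii: np.ndarray,
    rng: np.random.Generator | None = None,
    params: ParameterSet | None = None,
    regions: PlasticityRegions | None = None,
    act0: Tuple[np.ndarray, np.ndarray] | None = None,
    chain: PlasticityChain | None = None,
):
    """Run the full readout over enzyme activity trajectories.

    ``can``/``camkii`` have shape (n_t,) or (n_samples, n_t); the trajectories
    are consumed on their own grid ``t`` (uniform spacing expected).  Returns
    ``(weights, act_p, act_d, chain)`` where ``weights`` is the per-sample
    weight change (%) at the end and ``act_p``/``act_d`` the final
    activations.
    """
    p = params or default_params()
    regions = regions or default_regions()
    can = np.atleast_2d(np.asarray(can, dtype=float))
    camkii = np.atleast_2d(np.asarray(camkii, dtype=float))
    n_samples, n_t = can.shape
    t = np.asarray(t, dtype=float)
    if t.size != n_t:
        raise ValueError("time grid does not match trajectories")
    if chain is None:
        chain = PlasticityChain.initial(n_samples, int(p["n_processes"]))
    act_p = np.zeros(n_samples) if act0 is None else np.asarray(act0[0], float)
    act_d = np.zeros(n_samples) if act0 is None else np.asarray(act0[1], float)

    # membership of every trajectory point, evaluated in one vectorised pass
    in_p_all, in_d_all = regions.indicators(can.ravel(), camkii.ravel())
    in_p_all = in_p_all.reshape(n_samples, n_t)
    in_d_all = in_d_all.reshape(n_samples, n_t)

    # the chain rates are bounded by 1/t_P and vary on the multi-second
    # timescale of the activations, so the chain is resampled on chunks of
    # ~10 grid steps using the rates integrated over the chunk (the act
    # variables themselves advance exactly on every grid step)
    chunk = 10
    lam_p = np.zeros(n_samples)
    lam_d = np.zeros(n_samples)
    span = 0.0
    for i in range(1, n_t):
        dt = t[i] - t[i - 1]
        act_p = activation_step(act_p, in_p_all[:, i], p["a_P"], p["b_P"], dt)
        act_d = activation_step(act_d, in_d_all[:, i], p["a_D"], p["b_D"], dt)
        pr, dr = plasticity_rates(act_p, act_d, p)
        lam_p += pr * dt
        lam_d += dr * dt
        span += dt
        if i % chunk == 0 or i == n_t - 1:
            if span > 0 and (lam_p.any() or lam_d.any()):
                step_chain(chain, lam_p / span, lam_d / span, span, rng)
            lam_p[:] = 0.0
            lam_d[:] = 0.0
            span = 0.0

    return weight_change(chain), act_p, act_d, chain
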