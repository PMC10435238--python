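"""Post-processing: exponential decay fits, dwell-time maps, outcome statistics.

These are the quantities the experimental literature reports for this system:
decay time constants of receptor / enzyme activity traces (single-exponential
fits, as fluorescence studies do), mean weight-change statistics over repeated
protocol samples, and the mean-dwell-time histogram of the joint
(CaN, CaMKII) trajectory in the activity plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FitError", "fit_decay", "DwellMap", "dwell_map",
    "OutcomeStats", "summarize_outcomes", "sweep_protocols",
]


class FitError(RuntimeError):
    """Raised when a decay fit is requested on a trace that does not decay."""


def fit_decay(
    t: np.ndarray,
    y: np.ndarray,
    baseline: float | None = None,
    window: Tuple[float, float] | None = None,
) -> Tuple[float, Dict[str, float]]:
    """Fit ``y(t) = a * exp(-t * b) + baseline`` and return ``(tau, info)``.

    Parameters
    ----------
    t, y:
        Time stamps (s) and trace values.  The fit is performed from the
        maximum of the (windowed) trace onward, which is how decay constants
        are extracted from post-stimulus fluorescence traces.
    baseline:
        Value the trace decays to.  If ``None``, the final 5% of the trace is
        used as an estimate.
    window:
        Optional ``(t_start, t_stop)`` restriction applied before fitting.

    Returns
    -------
    tau:
        Decay time constant ``1/b`` in the units of ``t``.
    info:
        ``{"a": ..., "b": ..., "residual": ...}`` where ``residual`` is the
        RMS misfit relative to the fitted amplitude; a large value flags a
        trace that is not mono-exponential.

    Raises
    ------
    FitError
        If the trace does not decay (non-positive fitted rate, or no dynamic
        range above the baseline).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if window is not None:
        keep = (t >= window[0]) & (t <= window[1])
        t, y = t[keep], y[keep]
    if t.size < 4:
        raise FitError("not enough points for a decay fit")
    if baseline is None:
        tail = max(3, t.size // 20)
        baseline = float(np.mean(y[-tail:]))
    i0 = int(np.argmax(y))
    t_fit = t[i0:] - t[i0]
    y_fit = y[i0:] - baseline
    amp = y_fit[0]
    if not np.isfinite(amp) or amp <= 0 or amp <= 1e-12 * max(1.0, abs(baseline)):
        raise FitError("trace has no dynamic range above baseline")

    # log-linear seed using the upper part of the decay
    pos = y_fit > 0.05 * amp
    if pos.sum() < 3:
        pos = y_fit > 0
    if pos.sum() < 3:
        raise FitError("trace does not decay")
    slope, intercept = np.polyfit(t_fit[pos], np.log(y_fit[pos]), 1)
    b0 = -slope if slope < 0 else 1.0 / max(t_fit[-1], 1e-12)

    try:
        popt, _ = curve_fit(
            lambda tt, a, b: a * np.exp(-tt * b),
            t_fit, y_fit, p0=(amp, max(b0, 1e-12)), maxfev=20000,
        )
    except RuntimeError as err:
        raise FitError(f"decay fit did not converge: {err}") from err
    a, b = popt
    if b <= 0 or a <= 0:
        raise FitError("fitted trace is not decaying")
    resid = float(np.sqrt(np.mean((y_fit - a * np.exp(-t_fit * b)) ** 2)) / a)
    return 1.0 / b, {"a": float(a), "b": float(b), "residual": resid}


# ----------------------------------------------------------------------
# dwell-time map in the (CaN, CaMKII) plane
# ----------------------------------------------------------------------

@dataclass
class DwellMap:
    """Mean time (s) spent per (CaN, CaMKII) bin, averaged over samples."""

    hist: np.ndarray          # (n_can_bins, n_camkii_bins)
    can_edges: np.ndarray
    camkii_edges: np.ndarray

    @property
    def total_mass(self) -> float:
        return float(self.hist.sum())


def dwell_map(
    t: np.ndarray,
    can_trajs: Sequence[np.ndarray],
    camkii_trajs: Sequence[np.ndarray],
    bins: int | Tuple[np.ndarray, np.ndarray] = 50,
    ranges=None,
) -> DwellMap:
    """Histogram of mean dwell time of joint enzyme orbits.

    Each trajectory sample contributes its time step per visited bin; the
    result is averaged across samples, so the total mass equals the mean
    trajectory duration.
    """
    t = np.asarray(t, dtype=float)
    if len(can_trajs) != len(camkii_trajs) or len(can_trajs) == 0:
        raise ValueError("need equally many (non-zero) CaN and CaMKII trajectories")
    dt = np.empty_like(t)
    dt[:-1] = np.diff(t)
    dt[-1] = dt[-2] if t.size > 1 else 0.0

    if isinstance(bins, int):
        all_can = np.concatenate([np.asarray(c) for c in can_trajs])
        all_k = np.concatenate([np.asarray(c) for c in camkii_trajs])
        if ranges is None:
            ranges = (
                (0.0, max(all_can.max(), 1e-9)),
                (0.0, max(all_k.max(), 1e-9)),
            )
        can_edges = np.linspace(ranges[0][0], ranges[0][1] * (1 + 1e-9), bins + 1)
        k_edges = np.linspace(ranges[1][0], ranges[1][1] * (1 + 1e-9), bins + 1)
    else:
        can_edges, k_edges = (np.asarray(b) for b in bins)

    hist = np.zeros((can_edges.size - 1, k_edges.size - 1))
    for can, kam in zip(can_trajs, camkii_trajs):
        h, _, _ = np.histogram2d(
            np.asarray(can), np.asarray(kam),
            bins=(can_edges, k_edges), weights=dt,
        )
        hist += h
    hist /= len(can_trajs)
    return DwellMap(hist, can_edges, k_edges)


# ----------------------------------------------------------------------
# weight-change statistics
# ----------------------------------------------------------------------

@dataclass
class OutcomeStats:
    """Summary of per-sample weight changes (%) across a batch."""

    weights: np.ndarray
    mean: float
    median: float
    q25: float
    q75: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "mean": self.mean, "median": self.median,
            "q25": self.q25, "q75": self.q75,
            "n": int(self.weights.size),
        }


def sweep_protocols(
    specs: Sequence[str],
    conditions=None,
    n_samples: int = 20,
    seed: int = 0,
    **run_kwargs,
):
    """Mean weight change over a family of protocol strings.

    Each grid cell gets a seed keyed by ``(seed, cell index)``, so results do
    not depend on sweep order; returns a DataFrame with one row per protocol
    (outcome statistics columns).  A 1×1 grid reduces to a single batch run.
    """
    import pandas as pd

    from .engine import batch_run
    from .protocols import build_protocol

    rows = []
    for k, spec in enumerate(specs):
        cell_seed = int(np.random.SeedSequence([seed, k]).generate_state(1)[0]
                        % (2 ** 31))
        res = batch_run(build_protocol(spec), conditions,
                        n_samples=n_samples, seed=cell_seed, **run_kwargs)
        rows.append({"protocol": spec, **res.outcome.as_dict(),
                     "seed": cell_seed})
    return pd.DataFrame(rows)


def summarize_outcomes(weights: Iterable[float]) -> OutcomeStats:
    w = np.asarray(list(weights), dtype=float)
    if w.size == 0:
        raise ValueError("no outcomes to summarise")
    return OutcomeStats(
        weights=w,
        mean=float(np.mean(w)),
        median=float(np.median(w)),
        q25=float(np.percentile(w, 25)),
        q75=float(np.percentile(w, 75)),
    )
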