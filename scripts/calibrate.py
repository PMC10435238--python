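"""One-time calibration of the model's unit-ambiguous scale constants.

Two published magnitudes do not survive in print with usable units and are
therefore calibration constants of this implementation (stored in
``synaptor.params.DEFAULT_PARAMS``):

* ``ghk_scale`` — the absolute scale of the GHK calcium flux.  Anchor: a
  single presynaptic stimulation with successful glutamate release (no BaP)
  produces a ~3 µM peak free-calcium transient under the default conditions.
* ``bap_use_scale`` — the drive coupling somatic injections to the
  BaP-efficiency resource equations.  Anchor: the published use-dependent
  attenuation profile (dendritic BaP amplitude ≈ 85% of the first pulse by
  the 30th pulse of a 5 Hz train).

Run:  python scripts/calibrate.py
"""
import numpy as np

from synaptor.conditions import ExperimentalConditions
from synaptor.electrical import simulate_electrical
from synaptor.engine import RunConfig, simulate
from synaptor.protocols import build_protocol


def peak_calcium(ghk_scale: float, n_samples: int = 20, seed: int = 12345) -> float:
    cond = ExperimentalConditions(forced_release=True)
    cond = cond.with_(params=cond.params.replace(ghk_scale=ghk_scale))
    proto = build_protocol("1Pre")
    cfg = RunConfig(seed=seed, n_samples=n_samples, t_end=1.0,
                    record_channels=False)
    res = simulate(proto, cond, cfg)
    return float(res.records["ca"].max(axis=1).mean())


def attenuation_ratio(use_scale: float) -> float:
    cond = ExperimentalConditions()
    cond = cond.with_(params=cond.params.replace(bap_use_scale=use_scale))
    post = np.arange(30) / 5.0
    tr = simulate_electrical(post, cond, t_end=6.2)
    peaks = tr.pulse_peaks(post, "v_dend")
    return float(peaks[29] / peaks[0])


def bisect(fun, target, lo, hi, tol=0.005, it=25):
    flo, fhi = fun(lo) - target, fun(hi) - target
    assert flo * fhi < 0, (flo, fhi)
    for _ in range(it):
        mid = np.sqrt(lo * hi)
        fm = fun(mid) - target
        if abs(fm) < tol:
            return mid
        if fm * flo < 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return np.sqrt(lo * hi)


if __name__ == "__main__":
    print("calibrating ghk_scale toward 3 uM single-EPSP peak ...")
    for g in (0.02, 0.05, 0.1, 0.2):
        print(f"  ghk_scale={g:<6} peak Ca = {peak_calcium(g, 10):.3f} uM")
    print("calibrating bap_use_scale toward 85% 30th-pulse attenuation ...")
    for u in (2e5, 5e5, 1e6, 2e6):
        print(f"  use={u:g}  amp30/amp1 = {attenuation_ratio(u):.4f}")
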