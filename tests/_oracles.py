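"""Independent oracles shared by the unit and acceptance suites."""

import numpy as np

from synaptor.conditions import temperature_factors
from synaptor.enzymes import ENZYME_SPECIES
from synaptor.params import default_params

_I = {s: i for i, s in enumerate(ENZYME_SPECIES)}


def mass_action_derivatives(state: np.ndarray, ca: float, T: float) -> np.ndarray:
    """Generic mass-action evaluation of the CaM-CaMKII-CaN reaction table.

    Built reaction-by-reaction from the published table (species tuples,
    stoichiometry, calcium-dependent lumped rates) — independent of the
    hand-written production derivative function.
    """
    p = default_params()

    def adapt(a, b, c, d):
        return lambda cc: a * b / (c + d * cc)

    kf2C = adapt(p["kon_1C"], p["kon_2C"], p["koff_1C"], p["kon_2C"])
    kb2C = adapt(p["koff_1C"], p["koff_2C"], p["koff_1C"], p["kon_2C"])
    kf2N = adapt(p["kon_1N"], p["kon_2N"], p["koff_1N"], p["kon_2N"])
    kb2N = adapt(p["koff_1N"], p["koff_2N"], p["koff_1N"], p["kon_2N"])
    kfK2C = adapt(p["kon_K1C"], p["kon_K2C"], p["koff_K1C"], p["kon_K2C"])
    kbK2C = adapt(p["koff_K1C"], p["koff_K2C"], p["koff_K1C"], p["kon_K2C"])
    kfK2N = adapt(p["kon_K1N"], p["kon_K2N"], p["koff_K1N"], p["kon_K2N"])
    kbK2N = adapt(p["koff_K1N"], p["koff_K2N"], p["koff_K1N"], p["kon_K2N"])
    rho_k = temperature_factors(T, "CaMKII").rho_b
    rho_can = temperature_factors(T, "CaN")

    const = lambda k: (lambda cc: k)
    rxns = []
    for x, y, kf, kb in [
        ("CaM0", "CaM2C", kf2C, kb2C), ("CaM2N", "CaM4", kf2C, kb2C),
        ("CaM0", "CaM2N", kf2N, kb2N), ("CaM2C", "CaM4", kf2N, kb2N),
        ("KCaM0", "KCaM2C", kfK2C, kbK2C), ("KCaM2N", "KCaM4", kfK2C, kbK2C),
        ("KCaM0", "KCaM2N", kfK2N, kbK2N), ("KCaM2C", "KCaM4", kfK2N, kbK2N),
    ]:
        rxns.append(([x], [y], kf, 2))
        rxns.append(([y], [x], kb, 0))
    for x, y, kf, kb in [
        ("CaM0", "KCaM0", p["kf_CaM0"], p["kb_CaM0"]),
        ("CaM2C", "KCaM2C", p["kf_CaM2C"], p["kb_CaM2C"]),
        ("CaM2N", "KCaM2N", p["kf_CaM2N"], p["kb_CaM2N"]),
        ("CaM4", "KCaM4", p["kf_CaM4"], p["kb_CaM4"]),
    ]:
        rxns.append(([x, "mKCaM"], [y], const(kf), 0))
        rxns.append(([y], [x, "mKCaM"], const(kb), 0))
    rxns.append((["CaM4", "mCaN"], ["CaNCaM4"],
                 const(p["kf_CaN"] * rho_can.rho_f), 0))
    rxns.append((["CaNCaM4"], ["CaM4", "mCaN"],
                 const(p["kb_CaN"] * rho_can.rho_b), 0))
    for sfx in ("0", "2C", "2N", "4"):
        rxns.append(([f"PCaM{sfx}"], ["P", f"CaM{sfx}"],
                     const(p["k2_camkii"] * rho_k), 0))
    rxns.append((["P"], ["mKCaM"], const(p["k3_camkii"] * rho_k), 0))
    rxns.append((["P"], ["P2"], const(p["k4_camkii"]), 0))
    rxns.append((["P2"], ["P"], const(p["k5_camkii"] * rho_k), 0))

    d = np.zeros(len(ENZYME_SPECIES))
    for reactants, products, rate, ca_pow in rxns:
        flux = rate(ca) * ca ** ca_pow
        for r in reactants:
            flux = flux * state[_I[r]]
        for r in reactants:
            d[_I[r]] -= flux
        for pr in products:
            d[_I[pr]] += flux
    # phosphorylation is proportional to the activated-kinase fraction
    act = sum(state[_I[k]] for k in (
        "KCaM0", "KCaM2C", "KCaM2N", "KCaM4",
        "PCaM0", "PCaM2C", "PCaM2N", "PCaM4", "P", "P2"))
    for sfx in ("0", "2C", "2N", "4"):
        flux = p["k1_camkii"] * act / p["mKCaM_con"] * state[_I[f"KCaM{sfx}"]]
        d[_I[f"KCaM{sfx}"]] -= flux
        d[_I[f"PCaM{sfx}"]] += flux
    return d
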