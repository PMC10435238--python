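"""Channel Markov schemes, currents, and gating properties."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chisquare

from synaptor import channels as ch
from synaptor.jump import dwell_times, gillespie_path
from synaptor.params import default_params


def _assert_generator(Q):
    off = Q - np.diag(np.diag(Q))
    assert np.all(off >= 0)
    assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-9)


@pytest.mark.parametrize("builder", [
    lambda: ch.ampar_Q(0.0, 35.0), lambda: ch.ampar_Q(1000.0, 25.0),
    lambda: ch.nmdar_Q(0.0, 35.0), lambda: ch.nmdar_Q(500.0, 35.0, "GluN2B"),
    lambda: ch.gabar_Q(0.0, 25.0), lambda: ch.gabar_Q(1000.0, 35.0),
])
def test_rate_matrices_are_generators(builder):
    _assert_generator(builder())


def test_no_binding_without_ligand():
    assert ch.ampar_Q(0.0, 35.0)[0, 1] == 0.0
    assert ch.nmdar_Q(0.0, 35.0)[0, 1] == 0.0
    assert ch.nmdar_Q(0.0, 35.0, "GluN2B")[1, 2] == 0.0
    assert ch.gabar_Q(0.0, 35.0)[0, 1] == 0.0
    assert ch.gabar_Q(0.0, 35.0)[1, 2] == 0.0


def test_glun2b_rates_are_printed_fractions_of_glun2a():
    qa = ch.nmdar_Q(100.0, 35.0, "GluN2A")
    qb = ch.nmdar_Q(100.0, 35.0, "GluN2B")
    for i in range(6):
        assert qb[i, i + 1] == pytest.approx(0.25 * qa[i, i + 1])
        assert qb[i + 1, i] == pytest.approx(0.23 * qa[i + 1, i])


def test_ampar_current_reversal_and_linearity():
    counts = np.zeros(16)
    counts[list(ch.AMPA_OPEN)] = (0, 0, 1)  # one O4 channel
    assert ch.ampar_current(counts, 0.0) == 0.0
    assert ch.ampar_current(counts, -70.0) == pytest.approx(0.0365 * 70)
    assert ch.ampar_current(2 * counts, -70.0) == pytest.approx(
        2 * ch.ampar_current(counts, -70.0))
    assert ch.ampar_current(np.zeros(16), -70.0) == 0.0


def test_mg_block_values():
    assert ch.mg_block(-20.0, 0.0) == 1.0
    assert ch.mg_block(0.0, 1.0) == pytest.approx(0.781, abs=2e-3)
    assert ch.mg_block(-70.0, 1.0) == pytest.approx(0.0445, abs=2e-3)
    v = np.linspace(-90, 40, 40)
    b = ch.mg_block(v, 1.3)
    assert np.all(np.diff(b) > 0)


def test_gabar_current_sign_flips_with_age():
    from synaptor.conditions import erev_chloride

    counts = np.zeros(5)
    counts[3] = 2  # two receptors in O1
    young = ch.gabar_current(counts, -70.0, erev_chloride(5.0))
    adult = ch.gabar_current(counts, -70.0, erev_chloride(60.0))
    assert young > 0  # depolarising
    assert adult < 0  # hyperpolarising


def test_vgcc_gate_midpoints():
    # voltage midpoints of the unscaled activation/inactivation curves;
    # temperature factors then scale alpha and beta separately
    assert ch._t_type_minf(-32.0) == pytest.approx(0.5)
    assert ch._t_type_hinf(-70.0) == pytest.approx(0.5)
    rho_f = 2.503 - 0.304 / (1 + np.exp(1.048 * (35.0 - 30.668)))
    rho_b = 0.729 + 3.225 / (1 + np.exp(-0.330 * (35.0 - 36.279)))
    a, b = ch.vgcc_gate_rates(-32.0, 35.0, "T", "m")
    assert a / rho_f == pytest.approx(b / rho_b, rel=1e-9)
    alpha, _, _ = ch.vgcc_l_rates(13.7, 35.0)
    assert alpha == pytest.approx(0.83 / 2 * 1e3 * rho_f, rel=1e-6)


def test_sk_activation_and_current():
    p = default_params()
    assert ch.sk_activation(p["h_SK"]) == pytest.approx(0.5)
    assert ch.sk_current(0.7, -90.0) == 0.0
    assert ch.sk_current(0.5, -50.0) < 0  # hyperpolarising above reversal
    # at zero calcium the activation relaxes to zero
    assert ch.sk_derivative(0.2, 0.0, 35.0) < 0


def test_stationary_occupancy_matches_jump_engine(rng):
    """Frozen-ligand oracle: empirical state occupancy from the exact jump
    sampler matches the analytic stationary distribution (chi-square)."""
    Q = ch.gabar_Q(20.0, 25.0)  # low ligand keeps all states visited
    pi = ch.stationary_distribution(Q)
    times, states = gillespie_path(Q, 0, 20_000, rng)
    # occupancy weighted by sojourn time
    occ = np.zeros(Q.shape[0])
    for s, dt in zip(states[:-1], np.diff(times)):
        occ[s] += dt
    occ /= occ.sum()
    # compare via chi-square on time-discretised visits
    n_eff = 5000
    stat, pval = chisquare(np.round(occ * n_eff) + 1, pi * n_eff + 1)
    assert pval > 0.01


def test_ampar_desensitisation_recovery_monotone_in_interval():
    """Paired saturating pulses: the second pulse opens fewer receptors, and
    the recovery fraction grows with the inter-pulse interval."""
    T = 35.0
    Q_on = ch.ampar_Q(5000.0, T)
    Q_off = ch.ampar_Q(0.0, T)
    p0 = np.zeros(16)
    p0[0] = 1.0
    P_pulse = expm(Q_on * 0.02)

    def peak_open(p):
        # fine-grained scan of open probability during a 20 ms pulse
        peaks = []
        probs = p.copy()
        P_step = expm(Q_on * 5e-4)
        for _ in range(40):
            probs = probs @ P_step
            peaks.append(probs[list(ch.AMPA_OPEN)].sum())
        return max(peaks)

    first = peak_open(p0)
    after_first = p0 @ P_pulse
    ratios = []
    for gap in (0.01, 0.05, 0.2, 1.0, 5.0):
        p_rec = after_first @ expm(Q_off * gap)
        ratios.append(peak_open(p_rec) / first)
    assert ratios[0] < 0.9
    assert np.all(np.diff(ratios) > 0)
    assert ratios[-1] > 0.9


def test_glun2b_to_glun2a_decay_ratio_near_five():
    taua = ch.occupancy_decay_tau(ch.nmdar_Q(1000.0, 35.0, "GluN2A"),
                                  ch.nmdar_Q(0.0, 35.0, "GluN2A"),
                                  ch.NMDA_OPEN, horizon=1.0, dt=2e-4)[0]
    taub = ch.occupancy_decay_tau(ch.nmdar_Q(1000.0, 35.0, "GluN2B"),
                                  ch.nmdar_Q(0.0, 35.0, "GluN2B"),
                                  ch.NMDA_OPEN, horizon=3.0, dt=2e-4)[0]
    assert taub / taua == pytest.approx(5.0, rel=0.25)
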