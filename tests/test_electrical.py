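"""Somatic spike machinery, BaP propagation and use-dependent attenuation."""

import numpy as np
import pytest
from scipy.stats import binom

from synaptor.conditions import ExperimentalConditions
from synaptor.electrical import (adaptation_derivatives, bap_injection,
                                 evoked_ap_times, g_bap_adapt,
                                 simulate_electrical, soma_gate_rates,
                                 soma_gate_steady)
from synaptor.presynapse import release_probability


class TestSomaGateRates:
    def test_alpha_m_removable_singularity(self):
        # 0.4 (v+30)/(1-e^{-(v+30)/7.2}) -> 0.4*7.2 ms^-1 at v = -30
        am, *_ = soma_gate_rates(-30.0)
        assert am == pytest.approx(0.4 * 7.2 * 1e3, rel=1e-6)
        # continuity just off the pole
        am_eps, *_ = soma_gate_rates(-30.0 + 1e-7)
        assert am_eps == pytest.approx(am, rel=1e-5)

    def test_n_steady_state_midpoint(self):
        *_, n_inf, _ = soma_gate_rates(13.0)
        assert n_inf == pytest.approx(0.5)

    def test_n_tau_floor(self):
        v = np.linspace(-120.0, 80.0, 401)
        *_, n_tau = soma_gate_rates(v)
        assert np.all(n_tau >= 2e-3 - 1e-12)

    def test_rates_nonnegative_over_voltage_grid(self):
        v = np.linspace(-120.0, 80.0, 401)
        am, bm, ah, bh, n_inf, n_tau = soma_gate_rates(v)
        for arr in (am, bm, ah, bh, n_inf, n_tau):
            assert np.all(arr >= 0)
        assert np.all((n_inf >= 0) & (n_inf <= 1))


def test_rest_is_a_fixed_point():
    trace = simulate_electrical([], ExperimentalConditions(), t_end=0.5)
    for v in (trace.v_sp, trace.v_dend, trace.v_soma):
        assert np.all(np.abs(v + 70.0) < 0.5)


def test_g_bap_adapt_product_form():
    assert g_bap_adapt(1.0, 230.3) == pytest.approx(40.0, abs=1e-6)
    assert g_bap_adapt(0.7, 230.3) == pytest.approx(28.0, abs=1e-6)
    assert g_bap_adapt(1.0, 1e9) == pytest.approx(5.0, abs=1e-6)


def test_bap_injection_rectangles_sum():
    post = np.array([0.1, 0.101])
    assert bap_injection(0.05, post, 100.0, 0.002) == 0.0
    assert bap_injection(0.1005, post, 100.0, 0.002) == 100.0
    assert bap_injection(0.1015, post, 100.0, 0.002) == 200.0  # overlap


def test_adaptation_recovers_at_rest():
    dlam, daux, dage = adaptation_derivatives(
        1.0, 1.0, 1.0, 0.0, ExperimentalConditions())
    assert dlam == daux == dage == 0.0
    dlam, _, _ = adaptation_derivatives(0.5, 1.0, 1.0, 0.0,
                                        ExperimentalConditions())
    assert dlam == pytest.approx(0.25)


class TestEvokedAP:
    def test_deterministic_extremes(self, rng):
        cond = ExperimentalConditions(ca_o=2.5)
        pre = np.arange(20) * 0.001  # rapid volley: v_evoke sums -> p ~ 1
        docked = np.full(20, 25)
        times = evoked_ap_times(pre, docked, cond, rng)
        assert times.size > 0
        # empty docked pool: release probability is 0, never evoke
        times = evoked_ap_times(pre, np.zeros(20), cond, rng)
        assert times.size == 0

    def test_evoke_probability_matches_binomial_tail(self):
        # one spike from rest: v_evoke = 1; evoke iff > 80% of 25 succeed
        cond = ExperimentalConditions(ca_o=8.0)  # h small -> p large
        p = release_probability(1.0, 8.0, 25)
        expected = 1.0 - binom.cdf(20, 25, p)
        hits = sum(
            evoked_ap_times(np.array([0.0]), np.array([25]), cond,
                            np.random.default_rng(k)).size
            for k in range(4000)
        )
        assert hits / 4000 == pytest.approx(expected, abs=0.03)

    def test_evoked_ap_latency(self):
        cond = ExperimentalConditions(ca_o=8.0)
        for k in range(50):
            times = evoked_ap_times(np.array([0.25]), np.array([25]), cond,
                                    np.random.default_rng(k))
            if times.size:
                assert times[0] == pytest.approx(0.265)
                break
        else:
            pytest.fail("no evoked AP in 50 trials at high calcium")


class TestBaPPropagation:
    def test_soma_ap_overshoots_and_spine_depolarises(self):
        trace = simulate_electrical([0.05], ExperimentalConditions(),
                                    t_end=0.2)
        assert trace.v_soma.max() > 0.0
        assert trace.v_sp.max() - trace.v_sp[0] > 40.0
        assert np.all(np.abs(trace.v_soma) < 200.0)

    def test_dendritic_amplitude_decreases_with_distance(self):
        amps = []
        for d in (50.0, 150.0, 250.0, 400.0):
            cond = ExperimentalConditions(d_soma=d)
            tr = simulate_electrical([0.05], cond, t_end=0.2)
            amps.append(tr.pulse_peaks([0.05], "v_dend")[0])
        assert np.all(np.diff(amps) < 0)
        assert amps[-1] < amps[0]

    def test_five_baps_at_100hz_attenuate(self):
        post = 0.05 + np.arange(5) * 0.01
        tr = simulate_electrical(post, ExperimentalConditions(), t_end=0.3)
        peaks = tr.pulse_peaks(post, "v_dend", window=0.008)
        assert peaks[4] < peaks[0]

    def test_use_dependent_attenuation_at_5hz(self):
        post = np.arange(30) / 5.0
        tr = simulate_electrical(post, ExperimentalConditions(),
                                 t_end=post[-1] + 0.1)
        peaks = tr.pulse_peaks(post, "v_dend")
        ratio = peaks[29] / peaks[0]
        assert 0.7 < ratio < 0.95
        assert tr.lam.min() < 0.85  # the efficiency resource is consumed
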