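"""Geometric readout: regions, leaky activations, plasticity Markov chain."""

import numpy as np
import pytest
from scipy.linalg import expm

from synaptor.params import default_params
from synaptor.readout import (PlasticityChain, activation_step,
                              chain_step_probabilities, default_regions,
                              plasticity_rates, region_indicator, run_readout,
                              step_chain, weight_change)


class TestRegions:
    @pytest.mark.parametrize("point, expected", [
        ((8.0, 15.0), (1, 0)),      # well inside the LTP rectangle
        ((0.05, 0.1), (0, 0)),      # resting activity
        ((11.0, 15.0), (0, 0)),     # CaN beyond the LTP right edge
        ((2.0, 12.0), (0, 1)),      # inside the LTD hull
    ])
    def test_membership(self, point, expected):
        assert region_indicator(*point) == expected

    def test_boundary_counts_as_inside(self):
        assert region_indicator(6.35, 15.0) == (1, 1)  # shared edge

    def test_regions_do_not_overlap_in_their_interiors(self):
        rng = np.random.default_rng(0)
        can = rng.uniform(0.0, 12.0, 20000)
        kii = rng.uniform(0.0, 32.0, 20000)
        in_p, in_d = region_indicator(can, kii)
        both = (in_p == 1) & (in_d == 1)
        # only points on the shared CaN = 6.35 edge may be in both
        assert np.all(np.abs(can[both] - 6.35) < 1e-9)

    def test_polygons_are_simple(self):
        regions = default_regions()
        assert regions.ltp.is_valid and regions.ltd.is_valid
        assert regions.ltp.area > 0 and regions.ltd.area > 0
        # the LTD region abuts the LTP left edge at CaN = 6.35
        assert regions.ltd.bounds[2] == pytest.approx(6.35)


class TestActivation:
    def test_linear_growth_inside(self):
        act = activation_step(0.0, True, 200.0, 0.1, 1.5)
        assert act == pytest.approx(300.0)

    def test_exponential_decay_outside(self):
        act = activation_step(100.0, False, 200.0, 0.1, 3.0)
        assert act == pytest.approx(100.0 * np.exp(-0.3))

    def test_alternating_cycles_match_telescoping_sum(self):
        a, b = 200.0, 0.1
        act = 0.0
        for _ in range(10):
            act = activation_step(act, True, a, b, 1.0)
            act = activation_step(act, False, a, b, 1.0)
        # closed form: act_{k+1} = (act_k + a) e^{-b}
        expected = 0.0
        for _ in range(10):
            expected = (expected + a) * np.exp(-b)
        assert act == pytest.approx(expected, rel=1e-12)


class TestRates:
    def test_hill_midpoint_and_asymptotes(self):
        p = default_params()
        pr, dr = plasticity_rates(p["K_P"], 0.0)
        assert pr == pytest.approx(1.0 / (2 * 13.0))
        assert dr == 0.0
        pr, dr = plasticity_rates(0.0, 1e12)
        assert pr == 0.0
        assert dr == pytest.approx(1.0 / 18.0, rel=1e-6)


class TestChain:
    def test_counts_conserved_under_stochastic_stepping(self, rng):
        chain = PlasticityChain.initial(50, 100)
        for _ in range(200):
            step_chain(chain, 0.05, 0.02, 0.01, rng)
            assert np.all(chain.total == 100)
            assert np.all((chain.ltd >= 0) & (chain.nc >= 0) & (chain.ltp >= 0))

    def test_zero_rates_freeze_the_chain(self, rng):
        chain = PlasticityChain.initial(5, 100)
        for _ in range(50):
            step_chain(chain, 0.0, 0.0, 0.01, rng)
        assert np.all(chain.nc == 100)
        assert np.all(weight_change(chain) == 0.0)

    def test_strong_ltp_rate_absorbs_population(self, rng):
        chain = PlasticityChain.initial(20, 100)
        for _ in range(3000):
            step_chain(chain, 5.0, 0.0, 0.01, rng)
        assert np.all(chain.ltp == 100)
        assert np.all(weight_change(chain) == 100.0)

    def test_mean_counts_match_ctmc_matrix_exponential(self, rng):
        """Constant-rate chain vs the analytic CTMC oracle."""
        p_rate, d_rate, horizon = 0.08, 0.03, 5.0
        Q = np.array([
            [-p_rate, p_rate, 0.0],        # LTD -> NC
            [d_rate, -(p_rate + d_rate), p_rate],   # NC -> LTD / LTP
            [0.0, d_rate, -d_rate],        # LTP -> NC
        ])
        probs = np.array([0.0, 1.0, 0.0]) @ expm(Q * horizon)
        n_rep, n_proc = 400, 100
        chain = PlasticityChain.initial(n_rep, n_proc)
        for _ in range(int(horizon / 0.01)):
            step_chain(chain, p_rate, d_rate, 0.01, rng)
        means = np.array([chain.ltd.mean(), chain.nc.mean(),
                          chain.ltp.mean()]) / n_proc
        se = np.sqrt(probs * (1 - probs) / (n_rep * n_proc)) + 1e-4
        assert np.all(np.abs(means - probs) < 5 * se + 0.005)

    def test_exact_step_probabilities(self):
        a, b, c, d = chain_step_probabilities(0.3, 0.1, 0.5)
        esc = 1.0 - np.exp(-0.4 * 0.5)
        assert a == pytest.approx(esc * 0.75)
        assert b == pytest.approx(esc * 0.25)
        assert c == pytest.approx(1.0 - np.exp(-0.15))
        assert d == pytest.approx(1.0 - np.exp(-0.05))


class TestRunReadout:
    def test_longer_ltp_dwell_gives_larger_ltp_count(self):
        """Coupling: holding the orbit inside the LTP region longer yields a
        stochastically larger final LTP count (paired seeds)."""
        t = np.arange(0.0, 120.0, 0.01)
        can = np.full_like(t, 8.0)
        kii = np.full_like(t, 15.0)
        short = can.copy()
        short[t > 20.0] = 0.0     # leaves the region after 20 s
        wins = 0
        for k in range(60):
            rng1 = np.random.default_rng(500 + k)
            rng2 = np.random.default_rng(500 + k)
            w_long, *_ = run_readout(t, can, kii, rng=rng1)
            w_short, *_ = run_readout(t, short, kii, rng=rng2)
            wins += int(w_long[0] >= w_short[0])
        assert wins >= 55

    def test_resting_orbit_gives_no_change(self, rng):
        t = np.arange(0.0, 60.0, 0.01)
        w, act_p, act_d, chain = run_readout(
            t, np.full_like(t, 0.01), np.full_like(t, 5.0), rng=rng)
        assert w[0] == 0.0
        assert act_p[0] == 0.0 and act_d[0] == 0.0
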