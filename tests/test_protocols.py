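"""Protocol grammar, jitter/sparsity/Poisson variability."""

import numpy as np
import pytest
from scipy.stats import kstest, norm

from synaptor.protocols import (Protocol, ProtocolError, apply_jitter,
                                apply_sparsity, build_protocol,
                                poisson_protocol, preset_conditions)


class TestGrammar:
    def test_standard_pairing(self):
        p = build_protocol("1Pre1Post10, 300 at 5 Hz")
        assert p.pre_times.size == 300
        assert np.allclose(np.diff(p.pre_times), 0.2)
        assert np.allclose(p.post_times - p.pre_times, 0.010)

    def test_post_doublet_pairing(self):
        p = build_protocol("1Pre2Post10, 300 at 5 Hz")
        assert p.post_times.size == 600
        # doublet: 10 ms delay then the default 10 ms intra-burst interval
        assert p.post_times[0] == pytest.approx(0.010)
        assert p.post_times[1] == pytest.approx(0.020)

    def test_anticausal_delay_measured_from_last_post(self):
        p = build_protocol("2Post1Pre50, 10 at 1 Hz")
        assert p.pre_times[0] == pytest.approx(p.post_times[1] + 0.050)

    def test_presynaptic_doublet_train(self):
        p = build_protocol("2Pre50, 900 at 3 Hz")
        assert p.pre_times.size == 1800
        assert p.pre_times[1] - p.pre_times[0] == pytest.approx(0.050)
        assert p.pre_times[2] - p.pre_times[0] == pytest.approx(1 / 3)

    def test_theta_burst_nesting(self):
        p = build_protocol(
            "4Pre at 100 Hz repeated 10 times at 5 Hz given in 6 epochs "
            "at 0.1 Hz")
        assert p.pre_times.size == 4 * 10 * 6
        assert p.pre_times[1] - p.pre_times[0] == pytest.approx(0.01)
        assert p.pre_times[4] - p.pre_times[0] == pytest.approx(0.2)

    def test_builders_are_pure(self):
        a = build_protocol("1Pre2Post10, 30 at 5 Hz")
        b = build_protocol("1Pre2Post10, 30 at 5 Hz")
        assert np.array_equal(a.pre_times, b.pre_times)
        assert np.array_equal(a.post_times, b.post_times)

    @pytest.mark.parametrize("bad", [
        "flurb", "1Pre1Post10 at Hz", "1Pre2Pre10", "", "300 at 5 Hz",
    ])
    def test_malformed_specs_raise(self, bad):
        with pytest.raises(ProtocolError):
            build_protocol(bad)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ProtocolError):
            Protocol(np.array([1.0, 0.5]), np.array([]))


class TestJitter:
    def test_zero_sigma_is_identity(self, rng):
        p = build_protocol("1Pre1Post10, 20 at 5 Hz")
        assert apply_jitter(p, 0.0, rng) is p

    def test_causality_inversion_fraction_matches_normal_oracle(self):
        # pre/post delay 10 ms, sigma = 50 ms each: the jittered delay is
        # N(10 ms, 2*(50 ms)^2); P(inverted) = Phi(-10/70.7) = 0.444
        # pairings 5 s apart, so sorting keeps pre/post pairs aligned
        p = build_protocol("1Pre1Post10, 200 at 0.2 Hz")
        inverted = 0
        total = 0
        for k in range(30):
            j = apply_jitter(p, 0.050, np.random.default_rng(k))
            inverted += int(np.sum(j.post_times < j.pre_times))
            total += p.pre_times.size
        expected = norm.cdf(-0.010 / (0.050 * np.sqrt(2)))
        assert inverted / total == pytest.approx(expected, abs=0.02)

    def test_mean_perturbation_unbiased(self, rng):
        p = build_protocol("1Pre, 500 at 5 Hz")
        j = apply_jitter(p, 0.01, rng)
        shift = j.pre_times - p.pre_times
        assert abs(shift.mean()) < 3 * 0.01 / np.sqrt(500)


class TestSparsity:
    def test_extremes(self, rng):
        p = build_protocol("1Pre1Post10, 50 at 5 Hz")
        assert apply_sparsity(p, 1.0, rng).pre_times.size == 0
        q = apply_sparsity(p, 0.0, rng)
        assert np.array_equal(q.pre_times, p.pre_times)

    def test_retained_count_within_binomial_ci(self):
        p = build_protocol("1Pre, 1000 at 5 Hz")
        kept = [apply_sparsity(p, 0.3, np.random.default_rng(k)).pre_times.size
                for k in range(20)]
        mean, sd = 700, np.sqrt(1000 * 0.3 * 0.7)
        assert abs(np.mean(kept) - mean) < 3 * sd / np.sqrt(20)


class TestPoisson:
    def test_zero_rate_empty(self, rng):
        p = poisson_protocol(0.0, 0.0, 10.0, rng)
        assert p.pre_times.size == 0 and p.post_times.size == 0

    def test_count_dispersion(self):
        counts = [poisson_protocol(10.0, 0.0, 10.0,
                                   np.random.default_rng(k)).pre_times.size
                  for k in range(200)]
        assert np.mean(counts) == pytest.approx(100, rel=0.05)
        assert np.var(counts) / np.mean(counts) == pytest.approx(1.0, abs=0.35)

    def test_interspike_intervals_exponential(self, rng):
        p = poisson_protocol(40.0, 0.0, 50.0, rng)
        isi = np.diff(p.pre_times)
        stat, pval = kstest(isi, "expon", args=(0, 1 / 40.0))
        assert pval > 0.01


def test_presets_resolve_to_conditions():
    cond = preset_conditions("tigaret2016")
    assert cond.temperature == 35.0 and cond.ca_o == 2.5
    cond = preset_conditions("fujii2013_25c", temperature=26.0)
    assert cond.forced_release and cond.mg_o == 0.0
    with pytest.raises(KeyError):
        preset_conditions("unknown_lab_1999")
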