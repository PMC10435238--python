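"""Hybrid engine: reproducibility, null behaviour, stream independence."""

import numpy as np
import pytest

from synaptor.conditions import ExperimentalConditions
from synaptor.engine import RunConfig, batch_run, simulate
from synaptor.protocols import build_protocol, poisson_protocol


@pytest.fixture(scope="module")
def small_run():
    proto = build_protocol("1Pre1Post10, 3 at 5 Hz")
    cfg = RunConfig(seed=42, n_samples=2, t_end=2.0)
    return simulate(proto, ExperimentalConditions(), cfg)


class TestReproducibility:
    def test_same_seed_same_output(self, small_run):
        proto = build_protocol("1Pre1Post10, 3 at 5 Hz")
        cfg = RunConfig(seed=42, n_samples=2, t_end=2.0)
        res2 = simulate(proto, ExperimentalConditions(), cfg)
        assert np.array_equal(small_run.weights, res2.weights)
        for k in small_run.records:
            assert np.array_equal(small_run.records[k], res2.records[k])

    def test_different_seed_changes_stochastic_draws(self, small_run):
        proto = build_protocol("1Pre1Post10, 3 at 5 Hz")
        res2 = simulate(proto, ExperimentalConditions(),
                        RunConfig(seed=43, n_samples=2, t_end=2.0))
        same = all(
            np.array_equal(a.released, b.released)
            for a, b in zip(small_run.presyn, res2.presyn))
        assert not same or not np.array_equal(
            small_run.records["ca"], res2.records["ca"])

    def test_release_stream_unaffected_by_channel_mode(self):
        """Counter-keyed streams: making the VGCCs deterministic must not
        shift the presynaptic release draws."""
        proto = build_protocol("1Pre, 10 at 5 Hz")
        cfg = dict(seed=11, n_samples=3, t_end=2.1)
        a = simulate(proto, ExperimentalConditions(), RunConfig(**cfg))
        b = simulate(proto,
                     ExperimentalConditions(
                         deterministic_sources=frozenset({"vgcc"})),
                     RunConfig(**cfg))
        for ta, tb in zip(a.presyn, b.presyn):
            assert np.array_equal(ta.released, tb.released)
            assert np.allclose(ta.glu_amp, tb.glu_amp)


class TestNullProtocol:
    def test_empty_protocol_stays_at_rest_with_zero_weight(self):
        proto = build_protocol("1Pre")  # single spike ...
        empty = proto.__class__(np.array([]), np.array([]), name="null")
        res = simulate(empty, ExperimentalConditions(),
                       RunConfig(seed=0, n_samples=2, t_end=10.0))
        assert np.all(np.abs(res.records["v_sp"] + 70.0) < 1.0)
        assert np.all(np.abs(res.records["v_soma"] + 70.0) < 1.0)
        assert np.all(res.weights == 0.0)
        # baseline calcium stays near its resting value (tonic T-type noise)
        assert res.records["ca"].mean() < 0.2


class TestBatch:
    def test_reported_mean_is_arithmetic_mean(self, small_run):
        stats = small_run.outcome
        assert stats.mean == pytest.approx(small_run.weights.mean())

    def test_batch_run_with_per_sample_protocols(self):
        rng = np.random.default_rng(0)
        protos = [poisson_protocol(2.0, 2.0, 1.0, rng) for _ in range(2)]
        res = batch_run(protos, ExperimentalConditions(), seed=3, t_end=2.0)
        assert res.weights.shape == (2,)
        assert res.can.shape[0] == 2


class TestDeterministicSources:
    def test_all_sources_deterministic_removes_sample_variance(self):
        cond = ExperimentalConditions(deterministic_sources=frozenset(
            {"presyn", "ampa", "nmda", "gaba", "vgcc", "plasticity"}))
        proto = build_protocol("1Pre1Post10, 2 at 5 Hz")
        res = simulate(proto, cond, RunConfig(seed=7, n_samples=2, t_end=1.5))
        for key in ("ca", "v_sp"):
            assert np.allclose(res.records[key][0], res.records[key][1])
        assert res.weights[0] == res.weights[1]


class TestPairedTransient:
    def test_pairing_calcium_exceeds_single_inputs(self):
        """A causal pre-post pairing yields a calcium transient larger than
        either the EPSP or the BaP alone (coincidence detection)."""
        cfg = dict(n_samples=6, t_end=1.2, record_channels=False)
        cond = ExperimentalConditions(forced_release=True)
        pair = build_protocol("1Pre1Post10")
        pre_only = build_protocol("1Pre")
        post_only = pair.__class__(np.array([]), pair.post_times, name="post")
        ca_pair = simulate(pair, cond, RunConfig(seed=1, **cfg))
        ca_pre = simulate(pre_only, cond, RunConfig(seed=1, **cfg))
        ca_post = simulate(post_only, cond, RunConfig(seed=1, **cfg))
        peak = lambda r: r.records["ca"].max(axis=1).mean()
        assert peak(ca_pair) > peak(ca_pre)
        assert peak(ca_pair) > peak(ca_post)

    def test_mg_free_medium_boosts_calcium(self):
        cond_hi = ExperimentalConditions(forced_release=True, mg_o=0.0)
        cond_lo = ExperimentalConditions(forced_release=True, mg_o=2.0)
        proto = build_protocol("1Pre")
        cfg = dict(n_samples=6, t_end=0.8, record_channels=False)
        hi = simulate(proto, cond_hi, RunConfig(seed=2, **cfg))
        lo = simulate(proto, cond_lo, RunConfig(seed=2, **cfg))
        assert hi.records["ca"].max() > lo.records["ca"].max()
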