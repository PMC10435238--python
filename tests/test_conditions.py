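"""Condition-dependent scalar functions: logistic curves, age/temperature/
calcium dependencies, and the parameter container."""

import math

import numpy as np
import pytest
import yaml

from synaptor.conditions import (ExperimentalConditions, bap_age_step,
                                 erev_chloride, gamma_nmda,
                                 nmda_subunit_counts, phi_dist,
                                 temperature_factors)
from synaptor.params import default_params


@pytest.mark.parametrize("T, mechanism, attr, expected, tol", [
    # logistic midpoints / evaluated curve values
    (31.724, "AMPA", "rho_f", 10.273 / 2, 1e-3),
    (30.668, "VGCC", "rho_f", 2.503 - 0.304 / 2, 1e-3),
    (45.475, "CaMKII", "rho_b", 162.171 - 161.426 / 2, 1e-3),
    (32.167, "GABA", "rho_b", 1.470 - 1.279 / 2, 1e-3),
])
def test_temperature_factor_values(T, mechanism, attr, expected, tol):
    pair = temperature_factors(T, mechanism)
    assert getattr(pair, attr) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize("mechanism", ["GABA", "CaMKII"])
def test_single_factor_mechanisms_return_unity_forward(mechanism):
    assert temperature_factors(35.0, mechanism).rho_f == 1.0


def test_unknown_mechanism_rejected():
    with pytest.raises(ValueError):
        temperature_factors(35.0, "kainate")


@pytest.mark.parametrize("mechanism, attr, sign", [
    ("AMPA", "rho_f", +1), ("AMPA", "rho_b", +1),
    ("NMDA", "rho_f", +1), ("NMDA", "rho_b", +1),
    ("VGCC", "rho_f", +1), ("VGCC", "rho_b", +1),
    ("SK", "rho_f", +1), ("CaMKII", "rho_b", +1),
    ("GABA", "rho_b", +1),
])
def test_temperature_factors_positive_and_monotone(mechanism, attr, sign):
    grid = np.linspace(18.0, 42.0, 49)
    vals = np.array([getattr(temperature_factors(t, mechanism), attr)
                     for t in grid])
    assert np.all(vals > 0)
    diffs = sign * np.diff(vals)
    assert np.all(diffs >= -1e-12)


class TestNmdaSubunitCounts:
    def test_midpoint_age(self):
        # r = 0.507 + 0.964/2 = 0.989 at the logistic midpoint
        assert nmda_subunit_counts(25.102, 0.0) == (8, 7)

    def test_adult_asymptote(self):
        assert nmda_subunit_counts(1e6, 0.0) == (10, 5)

    def test_total_is_fifteen_for_reference_ages(self):
        for age in (25.102, 1e6):
            a, b = nmda_subunit_counts(age, 0.0)
            assert a + b == 15

    def test_independent_rounding_bound(self):
        # independent rounding keeps the total within one receptor of 15
        for age in np.linspace(0, 90, 181):
            a, b = nmda_subunit_counts(age, 0.0)
            assert 14 <= a + b <= 16

    def test_noise_free_counts_are_piecewise_constant_stairs(self):
        ages = np.linspace(0.0, 80.0, 801)
        counts = np.array([nmda_subunit_counts(a, 0.0) for a in ages])
        # integer stair: many consecutive repeats, monotone drift of GluN2A up
        assert set(np.unique(np.diff(counts[:, 0]))) <= {0, 1}
        assert counts[0, 1] > counts[-1, 1]


def test_erev_chloride_curve():
    assert erev_chloride(0.691) == pytest.approx(-92.649 + 243.515 / 2, abs=0.01)
    assert erev_chloride(1e9) == pytest.approx(-92.649, abs=1e-6)
    assert erev_chloride(21.0) == pytest.approx(-59.5, abs=0.1)
    ages = np.linspace(0, 60, 121)
    vals = np.array([erev_chloride(a) for a in ages])
    assert np.all(np.diff(vals) < 0)


def test_gamma_nmda_curve():
    assert gamma_nmda(2.701) == pytest.approx(63.143, abs=0.01)
    assert gamma_nmda(1.8) == pytest.approx(90.79, abs=0.05)
    assert gamma_nmda(1e6) == pytest.approx(33.949, abs=1e-6)
    cas = np.linspace(0.5, 5.0, 50)
    vals = np.array([gamma_nmda(c) for c in cas])
    assert np.all(np.diff(vals) < 0)
    assert np.all((vals > 33.949) & (vals < 92.337))


def test_phi_dist_curve():
    assert phi_dist(230.3) == pytest.approx(0.8, abs=1e-9)
    assert phi_dist(0.0) == pytest.approx(1.486, abs=0.001)
    assert phi_dist(1e9) == pytest.approx(0.1, abs=1e-9)
    d = np.linspace(0, 600, 61)
    vals = np.array([phi_dist(x) for x in d])
    assert np.all(np.diff(vals) < 0)


def test_bap_age_step_curve():
    assert bap_age_step(16.482) == pytest.approx(1.391e-4 / 2, rel=1e-6)
    assert bap_age_step(0.0) == pytest.approx(
        1.391e-4 / (1 + math.exp(-0.135 * 16.482)), rel=1e-6)
    assert bap_age_step(1e9) == pytest.approx(0.0, abs=1e-12)
    ages = np.linspace(0, 60, 61)
    vals = np.array([bap_age_step(a) for a in ages])
    assert np.all(vals > 0) and np.all(np.diff(vals) < 0)


class TestExperimentalConditions:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ExperimentalConditions(ca_o=0.0)
        with pytest.raises(ValueError):
            ExperimentalConditions(age=-1.0)
        with pytest.raises(ValueError):
            ExperimentalConditions(deterministic_sources={"telepathy"})

    def test_out_of_range_temperature_warns_not_raises(self):
        with pytest.warns(UserWarning):
            ExperimentalConditions(temperature=10.0)

    def test_parameter_set_roundtrips_through_yaml(self, tmp_path):
        p = default_params()
        path = tmp_path / "params.yaml"
        path.write_text(yaml.safe_dump(dict(p)))
        restored = yaml.safe_load(path.read_text())
        assert restored == dict(p)

    def test_replace_rejects_unknown_symbols(self):
        with pytest.raises(KeyError):
            default_params().replace(not_a_parameter=1.0)
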