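"""Slab transmission: analytic Beer-Lambert and Monte Carlo estimators."""

import numpy as np
import pytest

from portalcontrast.materials import ELECTRON_REST_MEV, Material
from portalcontrast.spectra import BeamSpectrum
from portalcontrast.transport import (
    PhantomConfig,
    Slab,
    analytic_transmission,
    mc_transmission,
    optical_depth,
    read_phantom,
    write_phantom,
)
from portalcontrast.transport import _sample_compton_cos
from portalcontrast import fixtures as fx


def _mono(e=1.0):
    """A near-monoenergetic single-bin spectrum centred on ``e``."""
    return BeamSpectrum("mono", e * 1.001, False,
                        [e * 0.999, e * 1.001], [1.0])


class TestOpticalDepth:
    def test_empty_phantom_is_zero(self, materials, table):
        ph = PhantomConfig(slabs=[])
        assert optical_depth(ph, 1.0, materials, table) == 0.0

    def test_additive_over_subdivisions(self, materials, table):
        whole = PhantomConfig([Slab("water", 10.0)])
        split = PhantomConfig([Slab("water", 4.0), Slab("water", 6.0)])
        a = optical_depth(whole, 2.0, materials, table)
        b = optical_depth(split, 2.0, materials, table)
        assert a == pytest.approx(b, rel=1e-12)

    def test_ln2_slab(self, table, materials):
        mu = 0.070626  # water total at 1 MeV in the synthetic table
        x = np.log(2) / mu
        ph = PhantomConfig([Slab("water", x)])
        assert optical_depth(ph, 1.0, materials, table) == pytest.approx(
            0.6931, rel=1e-3
        )

    def test_unknown_material_rejected(self, materials, table):
        ph = PhantomConfig([Slab("vibranium", 1.0)])
        with pytest.raises(KeyError):
            optical_depth(ph, 1.0, materials, table)


class TestAnalytic:
    def test_empty_phantom_transmits_fully(self, materials, table):
        r = analytic_transmission(_mono(), PhantomConfig([]), materials, table)
        assert r.transmitted_signal == pytest.approx(1.0)
        assert r.statistical_uncertainty == 0.0

    def test_monoenergetic_half_value_layer(self, materials, table):
        mu = 0.070626
        ph = PhantomConfig([Slab("water", np.log(2) / mu)])
        r = analytic_transmission(_mono(1.0), ph, materials, table)
        assert r.transmitted_signal == pytest.approx(0.5, rel=1e-3)

    def test_two_bin_hand_value(self, materials, table):
        # equal weights at the same energy; one bin attenuated by ln 2 via
        # a half-value water slab would mix 1 and 0.5 -> 0.75.  Emulate by
        # averaging the two single-bin results.
        mu = 0.070626
        ph = PhantomConfig([Slab("water", np.log(2) / mu)])
        t_thin = analytic_transmission(_mono(1.0), PhantomConfig([]),
                                       materials, table).transmitted_signal
        t_thick = analytic_transmission(_mono(1.0), ph, materials,
                                        table).transmitted_signal
        assert 0.5 * (t_thin + t_thick) == pytest.approx(0.75, rel=1e-3)

    def test_signal_decreasing_in_thickness(self, materials, table,
                                            beam_suite):
        s = beam_suite["6MV-FF"]
        sig = [
            analytic_transmission(
                s, PhantomConfig([Slab("water", x)]), materials, table
            ).transmitted_signal
            for x in (5.0, 10.0, 20.0)
        ]
        assert sig[0] > sig[1] > sig[2]


class TestMonteCarloPrimary:
    def test_empty_phantom_exact(self, materials, table):
        r = mc_transmission(_mono(), PhantomConfig([]), materials, table,
                            n_histories=100, seed=1)
        assert r.transmitted_signal == 1.0

    def test_binomial_half_value(self, materials, table):
        mu = 0.070626
        ph = PhantomConfig([Slab("water", np.log(2) / mu)])
        r = mc_transmission(_mono(1.0), ph, materials, table,
                            n_histories=1_000_000, seed=3)
        assert abs(r.transmitted_signal - 0.5) < 3 * 5e-4

    def test_fixed_seed_bit_identical(self, materials, table, beam_suite):
        s = beam_suite["6MV-FFF"]
        ph = fx.make_replica_phantom(5.0, 7.5, 7.5, "soft_tissue")
        a = mc_transmission(s, ph, materials, table, 10_000, seed=11)
        b = mc_transmission(s, ph, materials, table, 10_000, seed=11)
        assert a.transmitted_signal == b.transmitted_signal
        assert a.statistical_uncertainty == b.statistical_uncertainty

    def test_requires_histories_and_seed(self, materials, table):
        with pytest.raises(ValueError):
            mc_transmission(_mono(), PhantomConfig([]), materials, table,
                            n_histories=0, seed=1)
        with pytest.raises(ValueError):
            mc_transmission(_mono(), PhantomConfig([]), materials, table,
                            n_histories=10, seed=None)


class TestMonteCarloScatter:
    def test_scatter_adds_buildup(self, materials, table, beam_suite):
        s = beam_suite["6MV-FFF"]
        ph = fx.make_replica_phantom(5.0, 7.5, 7.5, "soft_tissue")
        primary = analytic_transmission(
            s, ph, materials, table, weighting="photon_fluence"
        )
        scat = mc_transmission(s, ph, materials, table, 20_000, seed=5,
                               scatter=True, weighting="photon_fluence")
        assert scat.transmitted_signal > primary.transmitted_signal

    def test_compton_energies_within_kinematic_bounds(self):
        rng = np.random.default_rng(0)
        for e in (0.1, 0.511, 2.0, 6.0):
            alpha = np.full(5000, e / ELECTRON_REST_MEV)
            cos_t = _sample_compton_cos(alpha, rng)
            assert np.all(cos_t >= -1) and np.all(cos_t <= 1)
            e_new = e / (1 + alpha * (1 - cos_t))
            assert np.all(e_new <= e + 1e-15)
            assert np.all(e_new >= e / (1 + 2 * alpha[0]) - 1e-15)


def test_phantom_round_trip(tmp_path):
    ph = fx.make_replica_phantom()
    assert ph.total_thickness_cm == pytest.approx(20.0)
    p = tmp_path / "phantom.yaml"
    write_phantom(p, ph)
    back = read_phantom(p)
    assert back.slabs == list(ph.slabs)
    assert back.field_cm == ph.field_cm
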