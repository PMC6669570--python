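"""Cross-sections, mixture rule and material bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from portalcontrast.materials import (
    AttenuationTable,
    Material,
    MixtureSpec,
    THOMSON_CROSS_SECTION_CM2,
    compound_composition,
    compton_mass_atten,
    electrons_per_gram,
    klein_nishina_cross_section,
    mix_materials,
    partial_mass_atten,
    read_materials,
    total_mass_atten,
    write_materials,
)

WATER = Material("water", 1.0, {"H": 0.1119, "O": 0.8881})


class TestKleinNishina:
    @pytest.mark.parametrize(
        "energy, expected",
        [(0.511, 2.865e-25), (1.0, 2.112e-25)],
    )
    def test_closed_form_values(self, energy, expected):
        assert klein_nishina_cross_section(energy) == pytest.approx(
            expected, rel=1e-3
        )

    def test_thomson_limit(self):
        ratio = klein_nishina_cross_section(1e-6) / THOMSON_CROSS_SECTION_CM2
        assert ratio == pytest.approx(1.0, rel=1e-3)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-4, max_value=20.0),
           st.floats(min_value=1.01, max_value=10.0))
    def test_strictly_decreasing(self, e, factor):
        assert klein_nishina_cross_section(e) > klein_nishina_cross_section(
            e * factor
        )

    def test_rejects_nonpositive_energy(self):
        with pytest.raises(ValueError):
            klein_nishina_cross_section(0.0)


class TestElectronDensity:
    def test_water(self):
        assert electrons_per_gram(WATER) == pytest.approx(3.343e23, rel=1e-3)

    def test_pure_hydrogen(self):
        h = Material("hydrogen", 0.001, {"H": 1.0})
        assert electrons_per_gram(h) == pytest.approx(5.974e23, rel=1e-3)

    def test_invalid_fraction_sum_rejected(self):
        with pytest.raises(ValueError):
            Material("bad", 1.0, {"H": 0.5, "O": 0.4})

    def test_compton_product(self):
        assert compton_mass_atten(1.0, WATER) == pytest.approx(
            0.0706, rel=1e-3
        )

    def test_compton_depends_only_on_electron_density(self):
        # same Z/A -> same Compton coefficient, whatever the element mix
        a = Material("a", 1.0, {"C": 1.0})
        b = Material("b", 2.0, {"C": 1.0})
        assert compton_mass_atten(0.3, a) == compton_mass_atten(0.3, b)


def _power_law_table():
    # mu = 0.1 / E between 0.1 and 1.0 MeV: exact under log-log interpolation
    E = np.array([0.1, 1.0])
    return AttenuationTable(
        {
            "C": {
                "energy": E,
                "photoelectric": 0.1 / E,
                "incoherent": np.zeros(2),
                "pair": np.zeros(2),
            }
        }
    )


class TestPartialInterpolation:
    def test_power_law_exact_between_nodes(self):
        t = _power_law_table()
        q = 10 ** -0.5  # geometric midpoint of the grid
        assert partial_mass_atten(t, "C", q, "photoelectric") == pytest.approx(
            0.1 / q, rel=1e-12
        )

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=1.0))
    def test_power_law_exact_everywhere(self, q):
        t = _power_law_table()
        assert partial_mass_atten(t, "C", q, "photoelectric") == pytest.approx(
            0.1 / q, rel=1e-9
        )

    def test_node_identity(self, table):
        E0 = table._entry("Au")["energy"][37]
        v = table._entry("Au")["incoherent"][37]
        assert partial_mass_atten(table, "Au", E0, "incoherent") == v

    def test_pair_zero_below_threshold(self, table):
        assert partial_mass_atten(table, "Au", 1.0, "pair") == 0.0

    def test_out_of_range_rejected(self, table):
        with pytest.raises(ValueError):
            partial_mass_atten(table, "Au", 100.0, "incoherent")

    def test_unknown_element_and_channel(self, table):
        with pytest.raises(KeyError):
            partial_mass_atten(table, "Zz", 1.0, "incoherent")
        with pytest.raises(KeyError):
            partial_mass_atten(table, "Au", 1.0, "coherent")


class TestMixtureRule:
    def test_single_element_equals_channel_sum(self, table):
        gold = Material("Au", 19.32, {"Au": 1.0})
        total = total_mass_atten(2.0, gold, table)
        parts = sum(
            partial_mass_atten(table, "Au", 2.0, ch)
            for ch in ("photoelectric", "incoherent", "pair")
        )
        assert total == pytest.approx(parts, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1.0),
           st.floats(min_value=0.05, max_value=10.0))
    def test_linearity_in_mass_fractions(self, table, w, e):
        mix = Material("mix", 5.0, {"Au": w, "O": 1.0 - w})
        au = Material("au", 5.0, {"Au": 1.0})
        ox = Material("ox", 5.0, {"O": 1.0})
        expected = w * total_mass_atten(e, au, table) + (1 - w) * (
            total_mass_atten(e, ox, table)
        )
        assert total_mass_atten(e, mix, table) == pytest.approx(
            expected, rel=1e-12
        )

    def test_water_is_compton_dominated_at_1mev(self, table):
        assert total_mass_atten(1.0, WATER, table) == pytest.approx(
            compton_mass_atten(1.0, WATER), rel=0.02
        )


class TestMixMaterials:
    def test_zero_concentration_is_identity(self, materials):
        spec = MixtureSpec(materials["soft_tissue"], materials["Au"], 0.0)
        assert mix_materials(spec) is materials["soft_tissue"]

    def test_gold_at_40_mg_per_ml(self, materials):
        mixed = mix_materials(
            MixtureSpec(materials["soft_tissue"], materials["Au"], 40.0)
        )
        assert mixed.density == pytest.approx(1.10, abs=1e-12)
        assert mixed.composition["Au"] == pytest.approx(0.03636, rel=1e-3)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=100.0))
    def test_fractions_sum_to_one(self, materials, conc):
        mixed = mix_materials(
            MixtureSpec(materials["soft_tissue"], materials["Fe2O3"], conc)
        )
        assert sum(mixed.composition.values()) == pytest.approx(1.0, abs=1e-12)

    def test_negative_concentration_rejected(self, materials):
        with pytest.raises(ValueError):
            MixtureSpec(materials["soft_tissue"], materials["Au"], -1.0)


class TestCompoundComposition:
    @pytest.mark.parametrize(
        "stoich, expected",
        [
            ({"Fe": 2, "O": 3}, {"Fe": 0.6994, "O": 0.3006}),
            ({"H": 2, "O": 1}, {"H": 0.1119, "O": 0.8881}),
            ({"Au": 1}, {"Au": 1.0}),
        ],
    )
    def test_mass_fractions(self, stoich, expected):
        comp = compound_composition(stoich)
        for sym, w in expected.items():
            assert comp[sym] == pytest.approx(w, abs=2e-4)

    def test_unknown_element_rejected(self):
        with pytest.raises(KeyError):
            compound_composition({"Xx": 1})


def test_registry_round_trip(tmp_path, materials):
    path = tmp_path / "materials.yaml"
    write_materials(path, materials)
    back = read_materials(path)
    assert set(back) == set(materials)
    for key in materials:
        assert back[key].density == pytest.approx(materials[key].density)
        assert back[key].composition == pytest.approx(
            materials[key].composition
        )
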