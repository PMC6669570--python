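"""Synthetic inputs: attenuation tables, materials, phantom and beam suite.

Everything the simulation consumes is generated here from documented
parameterizations, so the full pipeline runs with no downloads.

Partial mass-attenuation channels per element:

* incoherent -- exact free-electron Klein-Nishina: sigma_KN(E) N_A Z / A;
* photoelectric -- power law  k_pe Z^4.5 / (A E^3)  with
  ``K_PE = 3.952e-8 cm^2 MeV^3 / g``, fixed once so that the soft-tissue
  photoelectric and incoherent coefficients cross near 0.05 MeV;
* pair -- k_pp (Z^2/A) max(0, ln(E / 1.022 MeV)) with ``K_PP = 5e-4``,
  keeping pair production a minor channel at 10 MV.

Absorption edges are not modelled; the tables are smooth in energy.  These
forms reproduce the qualitative interaction physics (photoelectric Z
dependence, Compton Z/A dependence, pair threshold) rather than any
evaluated cross-section library; absolute fidelity is deliberately
approximate.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .materials import (
    AVOGADRO,
    ELEMENTS,
    PAIR_THRESHOLD_MEV,
    AttenuationTable,
    Material,
    compound_composition,
    klein_nishina_cross_section,
    write_materials,
)
from .spectra import BeamSpectrum, generate_bremsstrahlung_spectrum, write_spectrum
from .transport import PhantomConfig, Slab, write_phantom

__all__ = [
    "K_PE",
    "K_PP",
    "build_attenuation_table",
    "make_default_materials",
    "make_replica_phantom",
    "make_beam_suite",
    "default_grid_config",
    "write_fixtures",
]

#: Photoelectric scale constant, cm^2 MeV^3 / g per Z^4.5/A (see module doc).
K_PE = 3.952e-8
#: Pair-production scale constant, cm^2/g per Z^2/A.
K_PP = 5.0e-4

#: ICRU-like four-component soft tissue (mass fractions).
SOFT_TISSUE_COMPOSITION = {"H": 0.101, "C": 0.111, "N": 0.026, "O": 0.762}
SOFT_TISSUE_DENSITY = 1.06  # g/cm^3

#: Bulk densities of the nanoparticle materials, g/cm^3.
NP_DENSITIES = {"Au": 19.32, "Pt": 21.45, "Ag": 10.49, "I": 4.93, "Fe2O3": 5.24}

#: Replica study grid: five materials, five concentrations, four beams.
GRID_MATERIALS = ("Au", "Pt", "I", "Ag", "Fe2O3")
GRID_CONCENTRATIONS = (3.0, 7.0, 18.0, 30.0, 40.0)  # mg/mL
BEAM_LABELS = ("6MV-FF", "6MV-FFF", "10MV-FF", "10MV-FFF")

# Frozen beam-model calibration (see docs/methods.md): flattening-filter
# thicknesses of the copper surrogate per nominal potential, the spectrum
# low-energy cutoff, and the tumour slab thickness of the replica phantom.
FF_FILTER_CM = {6.0: 0.36, 10.0: 0.7}
INHERENT_FILTER_CM = 0.1
SPECTRUM_E_MIN_MEV = 0.05
SPECTRUM_N_BINS = 200
TUMOUR_THICKNESS_CM = 14.0
PHANTOM_TOTAL_CM = 20.0


def build_attenuation_table(
    elements=None,
    e_min_mev: float = 0.01,
    e_max_mev: float = 12.0,
    n_grid: int = 120,
) -> AttenuationTable:
    """Partial mass-attenuation table on a log-spaced energy grid."""
    if elements is None:
        elements = sorted(ELEMENTS)
    if not 0 < e_min_mev < e_max_mev:
        raise ValueError("require 0 < e_min_mev < e_max_mev")
    E = np.geomspace(e_min_mev, e_max_mev, n_grid)
    kn = klein_nishina_cross_section(E)
    data = {}
    for sym in elements:
        rec = ELEMENTS[sym]  # KeyError for unknown elements
        data[sym] = {
            "energy": E,
            "photoelectric": K_PE * rec.Z**4.5 / (rec.A * E**3),
            "incoherent": kn * AVOGADRO * rec.Z / rec.A,
            "pair": K_PP
            * (rec.Z**2 / rec.A)
            * np.maximum(0.0, np.log(E / PAIR_THRESHOLD_MEV)),
        }
    return AttenuationTable(data)


def make_default_materials() -> dict[str, Material]:
    """Registry: soft tissue, water, the five nanoparticle materials, and
    the copper beam-filter surrogate."""
    mats = {
        "soft_tissue": Material(
            "soft_tissue", SOFT_TISSUE_DENSITY, SOFT_TISSUE_COMPOSITION
        ),
        "water": Material(
            "water", 1.0, compound_composition({"H": 2, "O": 1})
        ),
        "copper": Material("copper", 8.96, {"Cu": 1.0}),
        "Fe2O3": Material(
            "Fe2O3", NP_DENSITIES["Fe2O3"], compound_composition({"Fe": 2, "O": 3})
        ),
    }
    for sym in ("Au", "Pt", "Ag", "I"):
        mats[sym] = Material(sym, NP_DENSITIES[sym], {sym: 1.0})
    return mats


def make_replica_phantom(
    tumour_thickness_cm: float = 5.0,
    upstream_cm: float = 7.5,
    downstream_cm: float = 7.5,
    tumour_material: str = "tumour",
) -> PhantomConfig:
    """Three-slab replica phantom: tissue / tumour / tissue, 30 x 30 cm^2
    laterally with a 10 x 10 cm^2 field; defaults total 20 cm depth."""
    for x in (tumour_thickness_cm, upstream_cm, downstream_cm):
        if x <= 0:
            raise ValueError("slab thicknesses must be positive")
    return PhantomConfig(
        slabs=[
            Slab("soft_tissue", upstream_cm),
            Slab(tumour_material, tumour_thickness_cm),
            Slab("soft_tissue", downstream_cm),
        ],
        lateral_cm=(30.0, 30.0),
        field_cm=(10.0, 10.0),
    )


def make_beam_suite(
    table: AttenuationTable | None = None,
    materials: dict[str, Material] | None = None,
    e_min_mev: float = SPECTRUM_E_MIN_MEV,
    n_bins: int = SPECTRUM_N_BINS,
    ff_filter_cm: dict[float, float] | None = None,
    inherent_filter_cm: float = INHERENT_FILTER_CM,
) -> dict[str, BeamSpectrum]:
    """The four replica beam qualities keyed by label.

    FFF members share the FF target spectrum but skip the flattening
    filter, leaving them softer (lower mean energy, more weight below
    0.15 MeV).
    """
    if table is None:
        table = build_attenuation_table()
    if materials is None:
        materials = make_default_materials()
    if ff_filter_cm is None:
        ff_filter_cm = FF_FILTER_CM
    copper = materials["copper"]
    suite = {}
    for potential in (6.0, 10.0):
        for filtered in (True, False):
            t_ff = ff_filter_cm[potential] if filtered else 0.0
            label = f"{potential:g}MV-{'FF' if filtered else 'FFF'}"
            suite[label] = generate_bremsstrahlung_spectrum(
                potential,
                table=table,
                filter_material=copper,
                e_min=e_min_mev,
                n_bins=n_bins,
                inherent_filter_cm=inherent_filter_cm,
                flattening_filter_cm=t_ff,
                label=label,
            )
    return suite


def default_grid_config():
    """The frozen replica grid configuration (see docs/methods.md)."""
    from .pipeline import GridConfig

    half_tissue = (PHANTOM_TOTAL_CM - TUMOUR_THICKNESS_CM) / 2.0
    return GridConfig(
        materials=list(GRID_MATERIALS),
        concentrations=list(GRID_CONCENTRATIONS),
        beams=list(BEAM_LABELS),
        tumour_thickness_cm=TUMOUR_THICKNESS_CM,
        upstream_cm=half_tissue,
        downstream_cm=half_tissue,
        mode="analytic",
        weighting="photon_fluence",
        n_histories=100_000,
        seed=20190626,
    )


def write_fixtures(out_dir) -> dict[str, str]:
    """Write the attenuation table, material registry, phantom config and
    four spectrum files; returns the paths written."""
    os.makedirs(out_dir, exist_ok=True)
    table = build_attenuation_table()
    materials = make_default_materials()
    paths = {}
    p = os.path.join(out_dir, "attenuation_table.csv")
    table.to_csv(p)
    paths["attenuation_table"] = p
    p = os.path.join(out_dir, "materials.yaml")
    write_materials(p, materials)
    paths["materials"] = p
    p = os.path.join(out_dir, "phantom.yaml")
    write_phantom(p, make_replica_phantom(TUMOUR_THICKNESS_CM,
                                        (PHANTOM_TOTAL_CM - TUMOUR_THICKNESS_CM) / 2,
                                        (PHANTOM_TOTAL_CM - TUMOUR_THICKNESS_CM) / 2))
    paths["phantom"] = p
    for label, spec in make_beam_suite(table, materials).items():
        p = os.path.join(out_dir, f"spectrum_{label}.txt")
        write_spectrum(spec, p)
        paths[label] = p
    return paths
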