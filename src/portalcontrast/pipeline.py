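"""Orchestration of the material x concentration x beam study grid.

For every grid cell the tumour slab is loaded with the requested
nanoparticle material at the requested concentration, the transmitted
signal is computed (analytic Beer-Lambert by default, Monte Carlo on
request), and the imaging contrast ratio and percentage contrast
enhancement are derived against the all-tissue background beam by beam.
Results are returned as pandas DataFrames and optionally written to CSV.

All Monte Carlo randomness flows from a single root seed: cell ``k`` (in
row-major material, concentration, beam order) uses
``numpy.random.SeedSequence((root_seed, k))``, so any cell can be
reproduced in isolation.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .contrast import (
    ComparisonResult,
    EnhancementSeries,
    enhancement_rate,
    imaging_contrast_ratio,
    percent_contrast_enhancement,
    relative_difference_percent,
)
from .materials import AttenuationTable, Material, MixtureSpec, mix_materials
from .spectra import BeamSpectrum
from .transport import analytic_transmission, mc_transmission
from . import fixtures as _fx

__all__ = ["GridConfig", "run_experiment_grid", "fit_series", "compare_beams"]

logger = logging.getLogger("portalcontrast")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass
class GridConfig:
    """Configuration of one full study grid."""

    materials: Sequence[str]
    concentrations: Sequence[float]
    beams: Sequence[str]
    tumour_thickness_cm: float = 5.0
    upstream_cm: float = 7.5
    downstream_cm: float = 7.5
    base_material: str = "soft_tissue"
    mode: str = "analytic"  # analytic | mc
    weighting: str = "photon_fluence"
    scatter: bool = False
    n_histories: int = 100_000
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.materials:
            raise ValueError("material list must not be empty")
        if not self.beams:
            raise ValueError("beam list must not be empty")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be >= 0")
        if self.mode not in ("analytic", "mc"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "GridConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _transmission(config, spectrum, phantom, materials, table, cell_index):
    if config.mode == "analytic":
        return analytic_transmission(
            spectrum, phantom, materials, table, weighting=config.weighting
        )
    seed = np.random.SeedSequence((config.seed, cell_index)).generate_state(1)[0]
    return mc_transmission(
        spectrum,
        phantom,
        materials,
        table,
        n_histories=config.n_histories,
        seed=int(seed) % 2**31,
        scatter=config.scatter,
        weighting=config.weighting,
    )


def run_experiment_grid(
    config: GridConfig,
    *,
    material_registry: Mapping[str, Material] | None = None,
    table: AttenuationTable | None = None,
    spectra: Mapping[str, BeamSpectrum] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full grid; returns (points, series) DataFrames.

    ``points`` has one row per (material, concentration, beam) with the
    transmitted signals, ICR and CE%; ``series`` has one row per
    (material, beam) with the fitted OLS enhancement rate.
    """
    if material_registry is None:
        material_registry = _fx.make_default_materials()
    if table is None:
        table = _fx.build_attenuation_table()
    if spectra is None:
        spectra = _fx.make_beam_suite(table, dict(material_registry))
    missing = [b for b in config.beams if b not in spectra]
    if missing:
        raise KeyError(f"unresolvable beam labels: {missing}")
    logger.info(
        "grid: %d materials x %d concentrations x %d beams, mode=%s "
        "weighting=%s tumour=%.3g cm seed=%d",
        len(config.materials), len(config.concentrations), len(config.beams),
        config.mode, config.weighting, config.tumour_thickness_cm, config.seed,
    )
    phantom = _fx.make_replica_phantom(
        config.tumour_thickness_cm, config.upstream_cm, config.downstream_cm
    )
    base = material_registry[config.base_material]
    mats = dict(material_registry)

    # background: tumour slab is plain base tissue
    backgrounds = {}
    n_cells = len(config.materials) * len(config.concentrations) * len(config.beams)
    for j, beam in enumerate(config.beams):
        mats["tumour"] = base
        backgrounds[beam] = _transmission(
            config, spectra[beam], phantom, mats, table, n_cells + j
        )

    rows = []
    cell = 0
    for m_name in config.materials:
        additive = material_registry[m_name]
        for conc in config.concentrations:
            tumour = mix_materials(MixtureSpec(base, additive, conc))
            for beam in config.beams:
                mats["tumour"] = tumour
                res = _transmission(
                    config, spectra[beam], phantom, mats, table, cell
                )
                I_b = backgrounds[beam].transmitted_signal
                icr = imaging_contrast_ratio(res.transmitted_signal, I_b)
                rows.append(
                    {
                        "material": m_name,
                        "concentration_mg_per_mL": conc,
                        "beam": beam,
                        "I_t": res.transmitted_signal,
                        "I_b": I_b,
                        "icr": icr,
                        "ce_percent": percent_contrast_enhancement(icr),
                        "uncertainty": res.statistical_uncertainty,
                    }
                )
                cell += 1
        logger.info("material %s done", m_name)
    points = pd.DataFrame(rows)
    series = fit_series(points)
    if config.output_dir:
        import os

        os.makedirs(config.output_dir, exist_ok=True)
        p1 = f"{config.output_dir}/contrast_points.csv"
        p2 = f"{config.output_dir}/enhancement_series.csv"
        points.to_csv(p1, index=False, float_format="%.9g")
        series.to_csv(p2, index=False, float_format="%.9g")
        logger.info("wrote %s and %s", p1, p2)
    return points, series


def fit_series(points: pd.DataFrame, force_origin: bool = False) -> pd.DataFrame:
    """OLS enhancement rate per (material, beam) series."""
    rows = []
    for (m, beam), g in points.groupby(["material", "beam"], sort=False):
        g = g.sort_values("concentration_mg_per_mL")
        ser = EnhancementSeries(
            material=m,
            beam_label=beam,
            concentrations=g["concentration_mg_per_mL"].tolist(),
            ce_percent=g["ce_percent"].tolist(),
        )
        fitted = enhancement_rate(ser, force_origin=force_origin)
        rows.append(
            {
                "material": m,
                "beam": beam,
                "slope_percent_per_mg_mL": fitted.slope,
                "intercept_percent": fitted.intercept,
                "ce_at_max_concentration": float(g["ce_percent"].iloc[-1]),
            }
        )
    return pd.DataFrame(rows)


#: The four headline beam comparisons: (label_a, label_b) pairs.
BEAM_COMPARISONS = (
    ("6MV-FFF", "6MV-FF"),
    ("10MV-FFF", "10MV-FF"),
    ("6MV-FF", "10MV-FF"),
    ("6MV-FFF", "10MV-FFF"),
)


def compare_beams(
    points: pd.DataFrame,
    material: str,
    concentration: float | None = None,
) -> list[ComparisonResult]:
    """Relative CE% differences between beam pairs at one concentration
    (the maximum on the grid by default)."""
    sel = points[points["material"] == material]
    if sel.empty:
        raise KeyError(f"material {material!r} not in results")
    if concentration is None:
        concentration = sel["concentration_mg_per_mL"].max()
    sel = sel[sel["concentration_mg_per_mL"] == concentration]
    ce = dict(zip(sel["beam"], sel["ce_percent"]))
    out = []
    for a, b in BEAM_COMPARISONS:
        if a not in ce or b not in ce:
            raise KeyError(f"missing grid cells for comparison {a} vs {b}")
        out.append(
            ComparisonResult(
                label_a=a,
                label_b=b,
                value_a=ce[a],
                value_b=ce[b],
                relative_difference=relative_difference_percent(ce[a], ce[b]),
            )
        )
    return out
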