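"""Imaging-contrast statistics built from transmitted signals.

The imaging contrast ratio compares the signal transmitted through the
tumour path, I_t, with the all-tissue background signal I_b:

    ICR = (I_t - I_b) / I_b.

Adding nanoparticles increases the tumour's attenuation, so I_t drops below
I_b and the ICR becomes negative; the percentage contrast enhancement is
reported as the magnitude of that deviation,

    CE% = 100 * |ICR - ICR_baseline|,

with the baseline ICR equal to zero because the nanoparticle-free tumour is
tissue-equivalent.  Concentration response is summarised by the ordinary
least-squares slope of CE% against concentration (%/mg/mL), and beam
qualities are compared by their relative difference in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ContrastPoint",
    "EnhancementSeries",
    "ComparisonResult",
    "imaging_contrast_ratio",
    "percent_contrast_enhancement",
    "enhancement_rate",
    "relative_difference_percent",
]


@dataclass(frozen=True)
class ContrastPoint:
    """CE% of one (material, concentration, beam) grid cell."""

    material: str
    concentration_mg_per_ml: float
    beam_label: str
    I_t: float
    I_b: float
    icr: float
    ce_percent: float

    def __post_init__(self) -> None:
        if self.I_b <= 0:
            raise ValueError("background signal must be positive")
        if self.ce_percent < 0:
            raise ValueError("contrast enhancement cannot be negative")


@dataclass
class EnhancementSeries:
    """CE% versus concentration for one material under one beam."""

    material: str
    beam_label: str
    concentrations: Sequence[float]
    ce_percent: Sequence[float]
    slope: float = float("nan")  # %/mg/mL
    intercept: float = float("nan")

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if len(c) and np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly ascending")


@dataclass(frozen=True)
class ComparisonResult:
    """Relative difference 100 * (a - b) / b between two beams' CE%."""

    label_a: str
    label_b: str
    value_a: float
    value_b: float
    relative_difference: float


def imaging_contrast_ratio(I_t: float, I_b: float) -> float:
    """(I_t - I_b) / I_b; zero iff the two signals coincide."""
    if I_b <= 0:
        raise ValueError("background signal must be positive")
    return (I_t - I_b) / I_b


def percent_contrast_enhancement(
    icr_np: float, icr_baseline: float = 0.0
) -> float:
    """100 * |ICR_np - ICR_baseline|; symmetric in its arguments.

    The absolute value is taken because added attenuation drives the ICR
    negative while enhancement is reported as a positive percentage.
    """
    return 100.0 * abs(icr_np - icr_baseline)


def enhancement_rate(
    series: EnhancementSeries, force_origin: bool = False
) -> EnhancementSeries:
    """Fit the CE%-versus-concentration slope by ordinary least squares.

    Returns a copy of the series with ``slope`` (%/mg/mL) and
    ``intercept`` filled in; ``force_origin`` constrains the intercept
    to zero.
    """
    c = np.asarray(series.concentrations, dtype=float)
    y = np.asarray(series.ce_percent, dtype=float)
    if len(c) < 2:
        raise ValueError("need at least two points to fit a rate")
    if np.ptp(c) == 0:
        raise ValueError("concentrations are all identical")
    if force_origin:
        slope = float(np.sum(c * y) / np.sum(c * c))
        intercept = 0.0
    else:
        slope, intercept = (float(v) for v in np.polyfit(c, y, 1))
    return EnhancementSeries(
        material=series.material,
        beam_label=series.beam_label,
        concentrations=list(series.concentrations),
        ce_percent=list(series.ce_percent),
        slope=slope,
        intercept=intercept,
    )


def relative_difference_percent(a: float, b: float) -> float:
    """100 * (a - b) / b."""
    if b == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (a - b) / b
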