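"""Parameterized megavoltage photon spectra for FF and FFF beams.

A linac photon spectrum is modelled as a thin-target bremsstrahlung
(Kramers) distribution filtered by exponential attenuation:

    phi(E)  proportional to  (E_max - E) / E * exp(-mu_f(E) * rho_f * t),

with ``t`` the total filter thickness (inherent plus flattening filter).
Removing the flattening filter (t_FF = 0) leaves the characteristic
low-energy excess of a flattening-filter-free (FFF) beam; adding it hardens
the beam, raising its mean energy.  No claim is made beyond these
qualitative orderings: real linac-head spectra require full treatment-head
simulation, which this package deliberately replaces with the closed form
above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import AttenuationTable, Material, total_mass_atten

__all__ = [
    "BeamSpectrum",
    "generate_bremsstrahlung_spectrum",
    "mean_energy",
    "fraction_below",
    "sample_energy",
    "read_spectrum",
    "write_spectrum",
]


@dataclass
class BeamSpectrum:
    """Binned relative photon fluence of one beam quality.

    ``bin_edges`` (MeV, strictly ascending, length n+1) and ``fluence``
    (length n, nonnegative) define a histogram; weights are normalised to
    sum to 1 on construction.
    """

    label: str
    nominal_potential_mv: float
    filtered: bool
    bin_edges: np.ndarray
    fluence: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.fluence = np.asarray(self.fluence, dtype=float)
        if self.bin_edges.ndim != 1 or len(self.bin_edges) < 2:
            raise ValueError("need at least one bin")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly ascending")
        if len(self.fluence) != len(self.bin_edges) - 1:
            raise ValueError("fluence length must match number of bins")
        if np.any(self.fluence < 0):
            raise ValueError("fluence weights must be nonnegative")
        total = self.fluence.sum()
        if total <= 0:
            raise ValueError("spectrum has no weight")
        if self.bin_edges[-1] > self.nominal_potential_mv + 1e-9:
            raise ValueError("top bin edge exceeds nominal potential")
        self.fluence = self.fluence / total

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)


def generate_bremsstrahlung_spectrum(
    e_max_mv: float,
    *,
    table: AttenuationTable,
    filter_material: Material,
    e_min: float = 0.05,
    n_bins: int = 200,
    inherent_filter_cm: float = 0.1,
    flattening_filter_cm: float = 0.0,
    label: str | None = None,
) -> BeamSpectrum:
    """Kramers spectrum with exponential filtration, binned and normalised.

    ``flattening_filter_cm = 0`` yields the FFF variant of the beam.
    Bins are log-spaced between ``e_min`` and ``e_max_mv``.
    """
    if not 0 < e_min < e_max_mv:
        raise ValueError("require 0 < e_min < e_max_mv")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if inherent_filter_cm < 0 or flattening_filter_cm < 0:
        raise ValueError("filter thicknesses must be >= 0")
    edges = np.geomspace(e_min, e_max_mv, n_bins + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    t = inherent_filter_cm + flattening_filter_cm
    mu = total_mass_atten(mid, filter_material, table) * filter_material.density
    phi = (e_max_mv - mid) / mid * np.exp(-mu * t)
    weights = phi * np.diff(edges)
    filtered = flattening_filter_cm > 0
    if label is None:
        label = f"{e_max_mv:g}MV-{'FF' if filtered else 'FFF'}"
    return BeamSpectrum(
        label=label,
        nominal_potential_mv=e_max_mv,
        filtered=filtered,
        bin_edges=edges,
        fluence=weights,
    )


def mean_energy(spectrum: BeamSpectrum) -> float:
    """Fluence-weighted mean of the bin midpoint energies, MeV."""
    return float(np.sum(spectrum.fluence * spectrum.midpoints))


def fraction_below(spectrum: BeamSpectrum, e_cut: float) -> float:
    """Fluence fraction below ``e_cut``, interpolating uniformly in-bin."""
    edges, w = spectrum.bin_edges, spectrum.fluence
    if e_cut <= edges[0]:
        return 0.0
    if e_cut >= edges[-1]:
        return 1.0
    covered = np.clip((e_cut - edges[:-1]) / np.diff(edges), 0.0, 1.0)
    return float(np.sum(w * covered))


def sample_energy(spectrum: BeamSpectrum, rng: np.random.Generator, size=None):
    """Draw energies: bins by weight, uniform within the chosen bin."""
    n = 1 if size is None else int(size)
    idx = rng.choice(len(spectrum.fluence), size=n, p=spectrum.fluence)
    lo = spectrum.bin_edges[idx]
    hi = spectrum.bin_edges[idx + 1]
    out = lo + rng.random(n) * (hi - lo)
    return float(out[0]) if size is None else out


def write_spectrum(spectrum: BeamSpectrum, path) -> None:
    """Two-column listing (bin upper edge MeV, fluence), '#' headers."""
    with open(path, "w") as fh:
        fh.write(f"# label: {spectrum.label}\n")
        fh.write(f"# nominal_potential_MV: {spectrum.nominal_potential_mv:g}\n")
        fh.write(f"# filtered: {int(spectrum.filtered)}\n")
        fh.write(f"# bottom_edge_MeV: {spectrum.bin_edges[0]:.17g}\n")
        for hi, w in zip(spectrum.bin_edges[1:], spectrum.fluence):
            fh.write(f"{hi:.17g} {w:.17e}\n")


def read_spectrum(path) -> BeamSpectrum:
    """Read a spectrum file; malformed lines are reported with their number."""
    meta: dict[str, str] = {}
    uppers: list[float] = []
    weights: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line.lstrip("#").partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            try:
                e, w = float(parts[0]), float(parts[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric entry {line!r}"
                ) from None
            if w < 0:
                raise ValueError(f"{path}:{lineno}: negative fluence weight")
            uppers.append(e)
            weights.append(w)
    try:
        bottom = float(meta["bottom_edge_MeV"])
        potential = float(meta["nominal_potential_MV"])
        filtered = bool(int(meta["filtered"]))
        label = meta["label"]
    except KeyError as exc:
        raise ValueError(f"{path}: missing header {exc}") from None
    edges = np.concatenate([[bottom], uppers])
    if np.any(np.diff(edges) <= 0):
        raise ValueError(f"{path}: bin edges not strictly ascending")
    return BeamSpectrum(
        label=label,
        nominal_potential_mv=potential,
        filtered=filtered,
        bin_edges=edges,
        fluence=np.asarray(weights),
    )
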