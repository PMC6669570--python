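"""Elements, materials and photon mass-attenuation coefficients.

Megavoltage photon attenuation is described per element by three partial
mass-attenuation channels -- photoelectric absorption, incoherent (Compton)
scattering and pair production -- tabulated on an energy grid and combined
for composites by the standard mixture rule

    (mu/rho)_mix(E) = sum_i w_i (mu/rho)_i(E),

where ``w_i`` are elemental mass fractions.  Coherent (Rayleigh) scattering
is insignificant at these energies and is not carried.

Nanoparticle-loaded tissue is built by :func:`mix_materials`: a concentration
``C`` in mg/mL adds ``C`` grams of additive per cm^3 of base material, so the
mixture density is ``rho_base + C`` (volume change neglected, a good
approximation below 40 mg/mL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

AVOGADRO = 6.02214076e23  # 1/mol
ELECTRON_REST_MEV = 0.51099895
CLASSICAL_ELECTRON_RADIUS_CM = 2.8179403262e-13
#: Thomson cross-section (8/3) pi r_e^2, the E -> 0 limit of Klein-Nishina.
THOMSON_CROSS_SECTION_CM2 = (
    8.0 / 3.0 * np.pi * CLASSICAL_ELECTRON_RADIUS_CM**2
)
#: Pair-production threshold 2 m_e c^2.
PAIR_THRESHOLD_MEV = 2.0 * ELECTRON_REST_MEV

#: Mass-fraction sum tolerance for a valid composition.
_FRACTION_TOL = 1e-9

CHANNELS = ("photoelectric", "incoherent", "pair")


@dataclass(frozen=True)
class ElementRecord:
    """A chemical element: symbol, atomic number Z, atomic mass A (g/mol)."""

    symbol: str
    Z: int
    A: float

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"atomic number must be >= 1, got {self.Z}")
        if self.A <= 0:
            raise ValueError(f"atomic mass must be positive, got {self.A}")


#: The elements this package needs: tissue/water constituents, the
#: nanoparticle metals, and copper (beam-filter surrogate).
ELEMENTS: dict[str, ElementRecord] = {
    e.symbol: e
    for e in [
        ElementRecord("H", 1, 1.008),
        ElementRecord("C", 6, 12.011),
        ElementRecord("N", 7, 14.007),
        ElementRecord("O", 8, 15.999),
        ElementRecord("Fe", 26, 55.845),
        ElementRecord("Cu", 29, 63.546),
        ElementRecord("Ag", 47, 107.868),
        ElementRecord("I", 53, 126.904),
        ElementRecord("Pt", 78, 195.084),
        ElementRecord("Au", 79, 196.967),
    ]
}


def _element(symbol: str) -> ElementRecord:
    try:
        return ELEMENTS[symbol]
    except KeyError:
        raise KeyError(f"unknown element {symbol!r}") from None


@dataclass(frozen=True)
class Material:
    """A homogeneous material: density (g/cm^3) and elemental mass fractions.

    Fractions must be in [0, 1] and sum to 1 within 1e-9.
    """

    name: str
    density: float
    composition: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if not self.composition:
            raise ValueError("composition must not be empty")
        for sym, w in self.composition.items():
            _element(sym)
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"mass fraction of {sym} out of [0,1]: {w}")
        total = sum(self.composition.values())
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ValueError(
                f"mass fractions of {self.name!r} sum to {total!r}, not 1"
            )
        object.__setattr__(self, "composition", dict(self.composition))


@dataclass(frozen=True)
class MixtureSpec:
    """Nanoparticle additive loaded into a base (tissue) at mg/mL."""

    base: Material
    additive: Material
    concentration_mg_per_ml: float

    def __post_init__(self) -> None:
        if self.concentration_mg_per_ml < 0:
            raise ValueError(
                f"concentration must be >= 0, got {self.concentration_mg_per_ml}"
            )


def compound_composition(stoichiometry: Mapping[str, int]) -> dict[str, float]:
    """Mass fractions of a stoichiometric compound, e.g. {'Fe': 2, 'O': 3}."""
    if not stoichiometry:
        raise ValueError("empty stoichiometry")
    masses = {}
    for sym, n in stoichiometry.items():
        if n < 1:
            raise ValueError(f"count for {sym} must be >= 1, got {n}")
        masses[sym] = n * _element(sym).A
    total = sum(masses.values())
    return {sym: m / total for sym, m in masses.items()}


def klein_nishina_cross_section(energy_mev):
    """Total Klein-Nishina cross-section per free electron (cm^2).

    Strictly decreasing in energy and approaching the Thomson value as
    E -> 0.  Accepts scalars or arrays; energies must be positive.
    """
    E = np.asarray(energy_mev, dtype=float)
    if np.any(E <= 0):
        raise ValueError("photon energy must be positive")
    a = E / ELECTRON_REST_MEV
    # The closed form loses precision to cancellation for very small alpha;
    # switch to the low-energy expansion there.
    small = a < 1e-4
    a_safe = np.where(small, 1.0, a)
    ln = np.log1p(2.0 * a_safe)
    term1 = (1 + a_safe) / a_safe**2 * (
        2 * (1 + a_safe) / (1 + 2 * a_safe) - ln / a_safe
    )
    term2 = ln / (2 * a_safe)
    term3 = (1 + 3 * a_safe) / (1 + 2 * a_safe) ** 2
    closed = 2 * np.pi * CLASSICAL_ELECTRON_RADIUS_CM**2 * (term1 + term2 - term3)
    series = THOMSON_CROSS_SECTION_CM2 * (1 - 2 * a + 5.2 * a**2)
    out = np.where(small, series, closed)
    return out if out.ndim else float(out)


def electrons_per_gram(material: Material) -> float:
    """Electron density N_A * sum_i w_i Z_i / A_i (electrons per gram)."""
    return AVOGADRO * sum(
        w * _element(sym).Z / _element(sym).A
        for sym, w in material.composition.items()
    )


def compton_mass_atten(energy_mev, material: Material):
    """Klein-Nishina (free-electron) Compton mass attenuation, cm^2/g."""
    return klein_nishina_cross_section(energy_mev) * electrons_per_gram(material)


class AttenuationTable:
    """Per-element partial mass-attenuation coefficients on an energy grid.

    Queries interpolate log-log linearly between grid nodes, which is exact
    for power-law channels.  Where a bracketing node is zero (the pair
    channel near its threshold) interpolation falls back to linear in log E
    on the raw values.  Queries outside the grid raise; the pair channel
    returns exactly 0 below the 1.022 MeV threshold.
    """

    def __init__(self, data: Mapping[str, Mapping[str, np.ndarray]]):
        self._data: dict[str, dict[str, np.ndarray]] = {}
        for sym, chans in data.items():
            _element(sym)
            E = np.asarray(chans["energy"], dtype=float)
            if E.ndim != 1 or len(E) < 2 or np.any(np.diff(E) <= 0):
                raise ValueError(
                    f"energy grid for {sym} must be strictly ascending"
                )
            entry: dict[str, np.ndarray] = {"energy": E}
            for ch in CHANNELS:
                v = np.asarray(chans[ch], dtype=float)
                if v.shape != E.shape:
                    raise ValueError(f"channel {ch} for {sym} has wrong shape")
                if np.any(v < 0):
                    raise ValueError(f"negative coefficients in {ch} for {sym}")
                if ch == "pair" and np.any(v[E < PAIR_THRESHOLD_MEV] > 0):
                    raise ValueError(
                        f"pair channel for {sym} nonzero below threshold"
                    )
                entry[ch] = v
            self._data[sym] = entry

    @property
    def elements(self) -> list[str]:
        return sorted(self._data)

    def energy_range(self, element: str) -> tuple[float, float]:
        E = self._entry(element)["energy"]
        return float(E[0]), float(E[-1])

    def _entry(self, element: str) -> dict[str, np.ndarray]:
        try:
            return self._data[element]
        except KeyError:
            raise KeyError(f"element {element!r} not in table") from None

    def partial(self, element: str, energy_mev, channel: str):
        """Partial mass-attenuation coefficient (cm^2/g) of one channel."""
        if channel not in CHANNELS:
            raise KeyError(f"unknown channel {channel!r}")
        entry = self._entry(element)
        E = entry["energy"]
        q = np.asarray(energy_mev, dtype=float)
        if np.any(q < E[0]) or np.any(q > E[-1]):
            raise ValueError(
                f"energy outside table range [{E[0]}, {E[-1]}] MeV for {element}"
            )
        v = entry[channel]
        hi = np.clip(np.searchsorted(E, q, side="left"), 1, len(E) - 1)
        lo = hi - 1
        E1, E2 = E[lo], E[hi]
        v1, v2 = v[lo], v[hi]
        t = np.log(q / E1) / np.log(E2 / E1)
        with np.errstate(divide="ignore", invalid="ignore"):
            loglog = np.where(
                (v1 > 0) & (v2 > 0),
                np.exp(
                    np.log(np.where(v1 > 0, v1, 1.0))
                    + t * np.log(np.where((v1 > 0) & (v2 > 0), v2 / v1, 1.0))
                ),
                v1 + t * (v2 - v1),
            )
        exact = np.isin(q, E)
        if np.any(exact):
            node = np.searchsorted(E, q, side="left")
            loglog = np.where(exact, v[np.clip(node, 0, len(E) - 1)], loglog)
        if channel == "pair":
            loglog = np.where(q < PAIR_THRESHOLD_MEV, 0.0, loglog)
        return loglog if loglog.ndim else float(loglog)

    def total_element(self, element: str, energy_mev):
        """Channel-summed mass attenuation of one element, cm^2/g."""
        return sum(self.partial(element, energy_mev, ch) for ch in CHANNELS)

    # -- plain-text round trip -------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sym in self.elements:
            e = self._data[sym]
            for i, E in enumerate(e["energy"]):
                rows.append(
                    {
                        "element": sym,
                        "energy_MeV": E,
                        "photoelectric_cm2_g": e["photoelectric"][i],
                        "incoherent_cm2_g": e["incoherent"][i],
                        "pair_cm2_g": e["pair"][i],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9e")

    @classmethod
    def from_csv(cls, path) -> "AttenuationTable":
        df = pd.read_csv(path)
        data = {}
        for sym, g in df.groupby("element", sort=False):
            g = g.sort_values("energy_MeV")
            data[str(sym)] = {
                "energy": g["energy_MeV"].to_numpy(),
                "photoelectric": g["photoelectric_cm2_g"].to_numpy(),
                "incoherent": g["incoherent_cm2_g"].to_numpy(),
                "pair": g["pair_cm2_g"].to_numpy(),
            }
        return cls(data)


def partial_mass_atten(
    table: AttenuationTable, element: str, energy_mev, channel: str
):
    """Functional alias for :meth:`AttenuationTable.partial`."""
    return table.partial(element, energy_mev, channel)


def total_mass_atten(energy_mev, material: Material, table: AttenuationTable):
    """Mixture-rule total mass attenuation of a material, cm^2/g.

    Exactly linear in the mass fractions: sum_i w_i sum_ch mu_ch(i, E).
    """
    total = 0.0
    for sym, w in material.composition.items():
        total = total + w * table.total_element(sym, energy_mev)
    return total


def partial_mass_atten_material(
    energy_mev, material: Material, table: AttenuationTable, channel: str
):
    """Mixture-rule partial mass attenuation for a single channel, cm^2/g."""
    total = 0.0
    for sym, w in material.composition.items():
        total = total + w * table.partial(sym, energy_mev, channel)
    return total


def mix_materials(spec: MixtureSpec) -> Material:
    """Load a nanoparticle additive into a base material at mg/mL.

    ``C`` mg/mL adds ``C/1000`` g of additive per cm^3 of base, so
    ``rho_mix = rho_base + C/1000`` and the additive's mass fraction is
    ``(C/1000)/rho_mix``; base fractions are rescaled to keep the sum at 1.
    At C = 0 the base material is returned unchanged.
    """
    c = spec.concentration_mg_per_ml * 1e-3  # g/cm^3
    if c == 0.0:
        return spec.base
    rho = spec.base.density + c
    w_add = c / rho
    comp: dict[str, float] = {
        sym: w * (1.0 - w_add) for sym, w in spec.base.composition.items()
    }
    for sym, w in spec.additive.composition.items():
        comp[sym] = comp.get(sym, 0.0) + w * w_add
    # renormalise away accumulated rounding so the invariant holds exactly
    total = sum(comp.values())
    comp = {sym: w / total for sym, w in comp.items()}
    name = (
        f"{spec.base.name}+{spec.additive.name}"
        f"@{spec.concentration_mg_per_ml:g}mg_mL"
    )
    return Material(name=name, density=rho, composition=comp)


# -- material registry files ---------------------------------------------


def write_materials(path, materials: Mapping[str, Material]) -> None:
    """Write a registry of materials as structured key/value text (YAML)."""
    doc = {
        key: {
            "density_g_cm3": float(m.density),
            "composition": {s: float(w) for s, w in m.composition.items()},
        }
        for key, m in materials.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_materials(path) -> dict[str, Material]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"malformed material registry {path}")
    return {
        key: Material(
            name=key,
            density=entry["density_g_cm3"],
            composition=entry["composition"],
        )
        for key, entry in doc.items()
    }
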