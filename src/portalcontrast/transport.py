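"""Photon transmission through a slab phantom.

The phantom is an ordered stack of homogeneous slabs along the beam axis
(z), laterally 30 x 30 cm^2 with a 10 x 10 cm^2 field in the replica
configuration.  Two computational routes produce the transmitted signal:

* :func:`analytic_transmission` -- exact spectrum-weighted Beer-Lambert
  transmission, evaluated at the spectrum's bin midpoints.  Deterministic;
  the default analysis path.
* :func:`mc_transmission` -- Monte Carlo estimate.  In primary-only mode
  each history survives the total optical depth with Beer-Lambert
  probability, so the estimator converges to the analytic value and serves
  as its statistical cross-check.  In scatter mode photons are tracked
  through free flights and Klein-Nishina Compton deflections until they
  escape, are absorbed (photoelectric or pair events terminate the history)
  or fall below a 0.01 MeV cutoff; photons crossing the exit plane inside
  the projected field are scored.

Scoring weights each photon either by its energy (``energy_fluence``) or
equally (``photon_fluence``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .materials import (
    ELECTRON_REST_MEV,
    AttenuationTable,
    Material,
    partial_mass_atten_material,
    total_mass_atten,
)
from .spectra import BeamSpectrum

__all__ = [
    "Slab",
    "PhantomConfig",
    "TransportResult",
    "optical_depth",
    "analytic_transmission",
    "mc_transmission",
    "read_phantom",
    "write_phantom",
    "write_results_csv",
]

WEIGHTINGS = ("energy_fluence", "photon_fluence")
ENERGY_CUTOFF_MEV = 0.01


@dataclass(frozen=True)
class Slab:
    material_name: str
    thickness_cm: float

    def __post_init__(self) -> None:
        if self.thickness_cm <= 0:
            raise ValueError("slab thickness must be positive")


@dataclass
class PhantomConfig:
    """Ordered slab stack along the beam axis plus lateral/field extent."""

    slabs: Sequence[Slab]
    lateral_cm: tuple[float, float] = (30.0, 30.0)
    field_cm: tuple[float, float] = (10.0, 10.0)

    @property
    def total_thickness_cm(self) -> float:
        return sum(s.thickness_cm for s in self.slabs)

    def with_material(self, old: str, new: str) -> "PhantomConfig":
        """A copy with every slab of material ``old`` renamed to ``new``."""
        return PhantomConfig(
            slabs=[
                Slab(new if s.material_name == old else s.material_name,
                     s.thickness_cm)
                for s in self.slabs
            ],
            lateral_cm=self.lateral_cm,
            field_cm=self.field_cm,
        )


@dataclass
class TransportResult:
    """Transmitted signal relative to the incident beam."""

    transmitted_signal: float
    statistical_uncertainty: float
    n_histories: int
    mode: str  # analytic | mc_primary | mc_scatter
    seed: int | None = None
    weighting: str = "energy_fluence"

    def __post_init__(self) -> None:
        if self.transmitted_signal < 0:
            raise ValueError("transmitted signal must be >= 0")


def _resolve(materials: Mapping[str, Material], name: str) -> Material:
    try:
        return materials[name]
    except KeyError:
        raise KeyError(f"unknown material {name!r}") from None


def optical_depth(
    phantom: PhantomConfig,
    energy_mev,
    materials: Mapping[str, Material],
    table: AttenuationTable,
):
    """Total optical depth sum_i (mu/rho)_i(E) rho_i x_i along the axis.

    Additive over slab subdivisions; an empty slab list gives 0.
    """
    od = np.zeros_like(np.asarray(energy_mev, dtype=float))
    for slab in phantom.slabs:
        m = _resolve(materials, slab.material_name)
        od = od + (
            total_mass_atten(energy_mev, m, table) * m.density * slab.thickness_cm
        )
    return od if od.ndim else float(od)


def _spectral_weights(spectrum: BeamSpectrum, weighting: str) -> np.ndarray:
    if weighting not in WEIGHTINGS:
        raise ValueError(f"unknown weighting {weighting!r}")
    w = spectrum.fluence.copy()
    if weighting == "energy_fluence":
        w = w * spectrum.midpoints
    return w / w.sum()


def analytic_transmission(
    spectrum: BeamSpectrum,
    phantom: PhantomConfig,
    materials: Mapping[str, Material],
    table: AttenuationTable,
    weighting: str = "energy_fluence",
) -> TransportResult:
    """Spectrum-weighted Beer-Lambert transmission at bin midpoints.

    T = sum_j c_j exp(-OD(E_j)) with c_j the normalised scoring weights
    (w_j E_j for energy fluence, w_j for photon fluence).
    """
    c = _spectral_weights(spectrum, weighting)
    od = optical_depth(phantom, spectrum.midpoints, materials, table)
    T = float(np.sum(c * np.exp(-np.asarray(od))))
    return TransportResult(
        transmitted_signal=T,
        statistical_uncertainty=0.0,
        n_histories=0,
        mode="analytic",
        seed=None,
        weighting=weighting,
    )


def _batch_ratio_se(num: np.ndarray, den: np.ndarray, n_batches: int) -> float:
    """Standard error of a ratio estimator from batch means."""
    n = len(num)
    n_batches = max(2, min(n_batches, n))
    cut = (n // n_batches) * n_batches
    bn = num[:cut].reshape(n_batches, -1).sum(axis=1)
    bd = den[:cut].reshape(n_batches, -1).sum(axis=1)
    ratios = np.divide(bn, bd, out=np.zeros_like(bn, dtype=float), where=bd > 0)
    return float(ratios.std(ddof=1) / np.sqrt(n_batches))


def mc_transmission(
    spectrum: BeamSpectrum,
    phantom: PhantomConfig,
    materials: Mapping[str, Material],
    table: AttenuationTable,
    n_histories: int,
    seed: int,
    scatter: bool = False,
    weighting: str = "energy_fluence",
    n_batches: int = 20,
) -> TransportResult:
    """Monte Carlo transmitted signal; see module docstring for the physics.

    Primary-only mode samples the spectrum on the same bin-midpoint
    discretisation as :func:`analytic_transmission`, so the two agree up to
    the reported statistical uncertainty.
    """
    if n_histories < 1:
        raise ValueError("n_histories must be >= 1")
    if seed is None:
        raise ValueError("mc_transmission requires an explicit seed")
    rng = np.random.default_rng(seed)
    if not phantom.slabs:
        return TransportResult(1.0, 0.0, n_histories,
                               "mc_scatter" if scatter else "mc_primary",
                               seed, weighting)
    if scatter:
        T, se = _mc_scatter(
            spectrum, phantom, materials, table, n_histories, rng,
            weighting, n_batches,
        )
        mode = "mc_scatter"
    else:
        c = _spectral_weights(spectrum, "photon_fluence")
        mids = spectrum.midpoints
        idx = rng.choice(len(c), size=n_histories, p=c)
        E = mids[idx]
        od_mid = np.asarray(optical_depth(phantom, mids, materials, table))
        survive = rng.random(n_histories) < np.exp(-od_mid[idx])
        w = E if weighting == "energy_fluence" else np.ones_like(E)
        T = float(np.sum(w * survive) / np.sum(w))
        se = _batch_ratio_se(w * survive, w, n_batches)
        mode = "mc_primary"
    return TransportResult(T, se, n_histories, mode, seed, weighting)


# -- scatter-mode transport ----------------------------------------------


def _sample_compton_cos(alpha: np.ndarray, rng: np.random.Generator):
    """Rejection-sample scattering angle cosines from the Klein-Nishina
    differential cross-section (unnormalised f = r^2 (r + 1/r - sin^2)
    with r = E'/E; f <= 2 everywhere)."""
    n = len(alpha)
    out = np.empty(n)
    todo = np.arange(n)
    while len(todo):
        c = rng.uniform(-1.0, 1.0, size=len(todo))
        r = 1.0 / (1.0 + alpha[todo] * (1.0 - c))
        f = r * r * (r + 1.0 / r - (1.0 - c * c))
        accept = rng.random(len(todo)) * 2.0 <= f
        out[todo[accept]] = c[accept]
        todo = todo[~accept]
    return out


def _rotate(direction: np.ndarray, cos_t: np.ndarray, phi: np.ndarray):
    """Rotate unit vectors by polar angle arccos(cos_t), azimuth phi."""
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    dx, dy, dz = direction[:, 0], direction[:, 1], direction[:, 2]
    # build an orthonormal frame around each direction
    tmp = np.sqrt(np.clip(1.0 - dz**2, 1e-20, None))
    u = np.stack([dx * dz / tmp, dy * dz / tmp, -tmp], axis=1)
    near_pole = np.abs(dz) > 1.0 - 1e-10
    u[near_pole] = [1.0, 0.0, 0.0]
    v = np.cross(direction, u)
    new = (
        direction * cos_t[:, None]
        + u * (sin_t * np.cos(phi))[:, None]
        + v * (sin_t * np.sin(phi))[:, None]
    )
    return new / np.linalg.norm(new, axis=1, keepdims=True)


def _mc_scatter(
    spectrum, phantom, materials, table, n_histories, rng, weighting, n_batches
):
    slabs = list(phantom.slabs)
    z_edges = np.concatenate([[0.0], np.cumsum([s.thickness_cm for s in slabs])])
    z_exit = z_edges[-1]
    half_x, half_y = phantom.lateral_cm[0] / 2, phantom.lateral_cm[1] / 2
    fx, fy = phantom.field_cm[0] / 2, phantom.field_cm[1] / 2
    mats = [_resolve(materials, s.material_name) for s in slabs]

    def mu_linear(slab_idx: np.ndarray, E: np.ndarray) -> np.ndarray:
        """Total linear attenuation (1/cm) per photon in its current slab."""
        out = np.empty_like(E)
        for k, m in enumerate(mats):
            sel = slab_idx == k
            if np.any(sel):
                out[sel] = total_mass_atten(E[sel], m, table) * m.density
        return out

    def channel_probs(slab_idx: np.ndarray, E: np.ndarray) -> np.ndarray:
        probs = np.empty((len(E), 3))
        for k, m in enumerate(mats):
            sel = slab_idx == k
            if np.any(sel):
                for j, ch in enumerate(("photoelectric", "incoherent", "pair")):
                    probs[sel, j] = partial_mass_atten_material(
                        E[sel], m, table, ch
                    )
        return probs / probs.sum(axis=1, keepdims=True)

    # pencil beam entering the stack at the origin along +z
    from .spectra import sample_energy

    E0 = sample_energy(spectrum, rng, size=n_histories)
    pos = np.zeros((n_histories, 3))
    dirn = np.tile([0.0, 0.0, 1.0], (n_histories, 1))
    E = E0.copy()
    slab_idx = np.zeros(n_histories, dtype=int)
    alive = np.ones(n_histories, dtype=bool)
    scored = np.zeros(n_histories)

    for _ in range(10_000):
        if not alive.any():
            break
        ia = np.flatnonzero(alive)
        xi = -np.log(rng.random(len(ia)))  # optical depth to next interaction
        p = pos[ia].copy()
        d = dirn[ia]
        e = E[ia]
        si = slab_idx[ia].copy()
        interact = np.zeros(len(ia), dtype=bool)
        done = np.zeros(len(ia), dtype=bool)
        # ray-trace through the slab stack until xi is used up or escape
        for _step in range(4 * len(slabs) + 40):
            act = ~done & ~interact
            if not act.any():
                break
            j = np.flatnonzero(act)
            mu = mu_linear(si[j], e[j])
            dz = d[j, 2]
            t_b = np.full(len(j), np.inf)
            fwd = dz > 1e-12
            bwd = dz < -1e-12
            t_b[fwd] = (z_edges[si[j][fwd] + 1] - p[j][fwd, 2]) / dz[fwd]
            t_b[bwd] = (z_edges[si[j][bwd]] - p[j][bwd, 2]) / dz[bwd]
            with np.errstate(divide="ignore", invalid="ignore"):
                tx = np.where(
                    np.abs(d[j, 0]) > 1e-12,
                    (np.sign(d[j, 0]) * half_x - p[j, 0]) / d[j, 0],
                    np.inf,
                )
                ty = np.where(
                    np.abs(d[j, 1]) > 1e-12,
                    (np.sign(d[j, 1]) * half_y - p[j, 1]) / d[j, 1],
                    np.inf,
                )
            t_lat = np.minimum(tx, ty)
            t_int = xi[j] / mu
            t = np.minimum(np.minimum(t_int, t_b), t_lat)
            p[j] += d[j] * t[:, None]
            xi[j] -= mu * t
            hit_int = t_int <= np.minimum(t_b, t_lat)
            interact[j[hit_int]] = True
            esc_lat = (~hit_int) & (t_lat < t_b)
            done[j[esc_lat]] = True  # lost through the side
            crossed = (~hit_int) & ~esc_lat
            cj = j[crossed]
            going_fwd = d[cj, 2] > 0
            si[cj] = si[cj] + np.where(going_fwd, 1, -1)
            out_front = si[cj] >= len(slabs)
            out_back = si[cj] < 0
            exit_idx = cj[out_front]
            if len(exit_idx):
                inside = (np.abs(p[exit_idx, 0]) <= fx) & (
                    np.abs(p[exit_idx, 1]) <= fy
                )
                ok = exit_idx[inside]
                scored[ia[ok]] = (
                    e[ok] if weighting == "energy_fluence" else 1.0
                )
            done[cj[out_front | out_back]] = True
            # nudge off the boundary to avoid re-detection
            p[cj, 2] = np.clip(p[cj, 2], 1e-12, z_exit - 1e-12)
        pos[ia] = p
        E[ia] = e
        slab_idx[ia] = si
        newly_dead = done
        alive[ia[newly_dead]] = False
        ii = ia[interact]
        if len(ii) == 0:
            continue
        # choose the interaction channel
        probs = channel_probs(slab_idx[ii], E[ii])
        u = rng.random(len(ii))
        compton = (u >= probs[:, 0]) & (u < probs[:, 0] + probs[:, 1])
        absorbed = ~compton  # photoelectric and pair both end the history
        alive[ii[absorbed]] = False
        ic = ii[compton]
        if len(ic) == 0:
            continue
        alpha = E[ic] / ELECTRON_REST_MEV
        cos_t = _sample_compton_cos(alpha, rng)
        E_new = E[ic] / (1.0 + alpha * (1.0 - cos_t))
        phi = rng.uniform(0.0, 2.0 * np.pi, size=len(ic))
        dirn[ic] = _rotate(dirn[ic], cos_t, phi)
        E[ic] = E_new
        low = E_new < ENERGY_CUTOFF_MEV
        alive[ic[low]] = False

    den = E0 if weighting == "energy_fluence" else np.ones_like(E0)
    T = float(scored.sum() / den.sum())
    se = _batch_ratio_se(scored, den, n_batches)
    return T, se


# -- config / result serialisation ---------------------------------------


def write_phantom(path, phantom: PhantomConfig) -> None:
    doc = {
        "slabs": [
            {"material": s.material_name, "thickness_cm": float(s.thickness_cm)}
            for s in phantom.slabs
        ],
        "lateral_cm": list(phantom.lateral_cm),
        "field_cm": list(phantom.field_cm),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_phantom(path) -> PhantomConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return PhantomConfig(
        slabs=[Slab(s["material"], s["thickness_cm"]) for s in doc["slabs"]],
        lateral_cm=tuple(doc.get("lateral_cm", (30.0, 30.0))),
        field_cm=tuple(doc.get("field_cm", (10.0, 10.0))),
    )


def write_results_csv(path, results: Mapping[str, TransportResult]) -> None:
    """One CSV row per labelled configuration."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["label", "mode", "weighting", "seed", "n_histories",
             "transmitted_signal", "statistical_uncertainty"]
        )
        for label, r in results.items():
            w.writerow(
                [label, r.mode, r.weighting, r.seed, r.n_histories,
                 f"{r.transmitted_signal:.9e}",
                 f"{r.statistical_uncertainty:.3e}"]
            )
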