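# portalcontrast

Simulation of portal-imaging contrast enhancement in nanoparticle-enhanced
radiotherapy.

In external-beam radiotherapy the megavoltage treatment beam itself is used
to acquire verification (portal) images through the patient. High atomic
number nanoparticles — gold, platinum, iodine, silver, iron oxide —
accumulated in a tumour increase its photon attenuation, chiefly through
the strongly Z-dependent photoelectric effect, and thereby darken the
tumour's shadow on the portal image. Because the photoelectric
cross-section grows steeply as photon energy falls, the effect is largest
for beams rich in low-energy photons: flattening-filter-free (FFF) beams
beat flattened (FF) beams, and 6 MV beats 10 MV. This package quantifies
those dependencies for a slab phantom with a nanoparticle-loaded tumour.

## Model

A beam quality is a binned relative fluence spectrum φ(E), generated from a
thin-target bremsstrahlung (Kramers) form with exponential filtration,

φ(E) ∝ (E_max − E)/E · exp(−μ_f(E) ρ_f t_filter),

where setting the flattening-filter thickness to zero yields the FFF
variant. The transmitted signal through the 30 × 30 × 20 cm³ slab phantom
(tissue / tumour / tissue along the beam axis, 10 × 10 cm² field) is the
spectrum-weighted Beer–Lambert transmission

T = Σ_j c_j exp(−Σ_i (μ/ρ)_i(E_j) ρ_i x_i) / Σ_j c_j,

with per-material mass attenuation built from per-element photoelectric,
incoherent (Klein–Nishina) and pair channels by the mixture rule
(μ/ρ)(E) = Σ w_i (μ/ρ)_i(E). A tumour loaded at concentration C mg/mL adds
C/1000 g/cm³ of nanoparticle material to the tissue. From the tumour-path
signal I_t and the all-tissue background signal I_b the imaging contrast
ratio and percentage contrast enhancement follow as

ICR = (I_t − I_b)/I_b,  CE% = 100 · |ICR − ICR_baseline|,

with the baseline ICR = 0 because the nanoparticle-free tumour is
tissue-equivalent. Concentration response is summarised by the ordinary
least-squares slope of CE% versus C, and beam qualities by relative CE%
differences. A Monte Carlo transport mode (primary-only, and analog
transport with Klein–Nishina Compton scattering) cross-checks the analytic
path and quantifies scatter build-up. See `docs/methods.md` for
assumptions, calibration and limitations.

## Worked example

```python
from portalcontrast import fixtures as fx
from portalcontrast.pipeline import run_experiment_grid, compare_beams

cfg = fx.default_grid_config()          # 5 materials x 5 concentrations x 4 beams
points, series = run_experiment_grid(cfg)

cell = points[(points.material == "Au")
              & (points.concentration_mg_per_mL == 40.0)
              & (points.beam == "6MV-FFF")].iloc[0]
print(f"I_t = {cell.I_t:.4f}  I_b = {cell.I_b:.4f}  "
      f"ICR = {cell.icr:+.4f}  CE = {cell.ce_percent:.1f}%")
for c in compare_beams(points, "Au"):
    print(f"{c.label_a:>8} vs {c.label_b:<8} -> {c.relative_difference:+.1f}%")
```

prints

```
I_t = 0.1675  I_b = 0.1983  ICR = -0.1549  CE = 15.5%
 6MV-FFF vs 6MV-FF   -> +39.9%
10MV-FFF vs 10MV-FF  -> +67.8%
  6MV-FF vs 10MV-FF  -> +56.3%
 6MV-FFF vs 10MV-FFF -> +30.3%
```

Gold at 40 mg/mL attenuates the 6 MV FFF beam 15.5% more than plain
tissue; removing the flattening filter raises gold's contrast enhancement
by ~40% at 6 MV, and the 6 MV FF beam outperforms 10 MV FF by ~56% —
softer spectra see more of the nanoparticles' photoelectric absorption.

The same grid is available from the shell:

```
portalcontrast make-fixtures --out fixtures
portalcontrast run-grid --out results
portalcontrast compare --results results/contrast_points.csv --material Au
```

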