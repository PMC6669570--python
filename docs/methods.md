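# Methods

## Physical model

Photon transmission through the phantom is polychromatic Beer–Lambert
attenuation: for each spectrum bin midpoint E_j the optical depth is the
sum over slabs of (μ/ρ)(E_j) · ρ · x, and the transmitted signal is the
scoring-weighted average of exp(−OD). Electrons set in motion by the
photons are not transported; the "signal" is the fluence of uncollided
photons reaching the exit plane (plus, in the Monte Carlo scatter mode,
Compton-scattered photons that still cross the exit plane inside the
projected field).

Mass attenuation is assembled per element from three channels:

- **incoherent** — exact free-electron Klein–Nishina cross-section times
  electron density N_A Z/A. Binding corrections (incoherent scattering
  function) are neglected, adequate above ~50 keV.
- **photoelectric** — k_pe Z^4.5 / (A E³) with
  k_pe = 3.952 × 10⁻⁸ cm² MeV³/g. The constant is fixed once so that the
  soft-tissue photoelectric and incoherent coefficients cross near
  0.05 MeV, which preserves the qualitative kilovoltage physics
  (photoelectric dominance at low E, steep Z dependence) inside a table
  that stays smooth in energy. Absorption edges (e.g. the Au K-edge near
  81 keV) are deliberately not modelled; megavoltage spectra put little
  weight there.
- **pair** — k_pp (Z²/A) max(0, ln(E/1.022 MeV)) with k_pp = 5 × 10⁻⁴,
  zero below the 2 m_e c² threshold and a minor channel at 10 MV, matching
  its subordinate role in the clinical energy range.

Coherent (Rayleigh) scattering is excluded as insignificant. Tables are
generated on a 120-point log grid over 0.01–12 MeV; queries interpolate
log-log linearly (exact for the power-law channels) and fall back to
linear-in-log-E where a bracketing node is zero (the pair channel at its
threshold). Out-of-grid queries are errors, never extrapolations.

Tissue is a four-component ICRU-like mixture (H 0.101, C 0.111, N 0.026,
O 0.762) at 1.06 g/cm³. Bulk nanoparticle densities are registry defaults
(Au 19.32, Pt 21.45, Ag 10.49, I 4.93, Fe₂O₃ 5.24 g/cm³); both are
configurable. Loading at C mg/mL adds C/1000 g/cm³ of additive:
ρ_mix = ρ_base + C/1000 with the volume change neglected — the natural
reading of mg-per-mL dosing, and exact to first order at ≤ 40 mg/mL. A
useful consequence: the tumour's optical-depth excess over tissue is
exactly (C/1000) · x · (μ/ρ)_additive(E), so contrast isolates the
additive's own attenuation.

## Beam model and calibration

Spectra are thin-target Kramers distributions filtered exponentially by a
copper surrogate (inherent filter 0.1 cm; flattening filter only for FF
beams), binned on 200 log-spaced bins from 0.05 MeV to the nominal
potential. This is the simplest form that reproduces both beam hardening
and the FFF low-energy excess; no fidelity is claimed beyond the
qualitative FF/FFF and 6/10 MV orderings, since real treatment-head
spectra require full linac simulation, which is out of scope.

Because the slab thicknesses inside the 20 cm stack and the true spectra
of the reference study are not published, the replica configuration was
calibrated once against its printed statistics by tuning only the tumour
thickness and the FF filter thicknesses, then frozen:

- tumour slab 14 cm (tissue 3 cm upstream and downstream; total 20 cm);
- FF filter 0.36 cm (6 MV) and 0.7 cm (10 MV) of the copper surrogate;
- spectrum floor E_min left at its 0.05 MeV default.

The thin filters relative to physical flattening filters compensate for
the Kramers form being much softer than a real linac target spectrum.

**Scoring weight.** The grid scores photon fluence at the exit plane
(every transmitted photon counts equally); energy-fluence weighting is
available as an option on every transmission function. Photon-fluence
scoring is the faithful reading of Beer–Lambert "intensity" for this
model and, empirically, is what reproduces the scale of the reference
statistics: under energy-fluence weighting the deep phantom's hardening
suppresses the contrast-carrying sub-0.5 MeV band so strongly that gold's
maximum enhancement cannot exceed ~7% under any sanctioned calibration,
versus the ~19% scale this configuration reproduces.

## Contrast statistics

CE% is defined as 100·|ICR| with a zero baseline: the nanoparticle-free
tumour is tissue-equivalent, so its ICR is identically zero and adding
attenuation drives ICR negative while enhancement is reported positive.
Concentration rates are ordinary least-squares slopes with free intercept
over the five grid concentrations (3, 7, 18, 30, 40 mg/mL); a
through-origin fit is available as a flag. Beam comparisons are relative
differences 100 (a − b)/b of CE% at the maximum grid concentration.

## Monte Carlo modes

Primary-only mode samples spectrum bins by weight, uses the same
bin-midpoint discretisation as the analytic estimator, and applies
Bernoulli survival with probability exp(−OD); it is the statistical
cross-check of the analytic path (agreement within 3 standard errors is a
tested property). Scatter mode performs analog transport: exponential free
paths in the slab's total linear attenuation, channel selection
proportional to the partial coefficients, Klein–Nishina angular sampling
by rejection (envelope 2, exact), Compton energy loss
E′ = E/(1 + α(1 − cos θ)), photoelectric and pair events terminating the
history (annihilation quanta are not tracked; their forward contribution
at these depths is small), a 0.01 MeV energy cutoff, and scoring of
photons crossing the exit plane within the 10 × 10 cm² field. Uncertainty
is the batch-means standard error of the ratio estimator (20 batches).
All randomness derives from `numpy` Generators; grid cell k under root
seed s uses `SeedSequence((s, k))`, so any cell is reproducible in
isolation. No variance reduction is implemented — histories are cheap at
this scale (~10⁶ primary histories in well under a second).

## What the synthetic generator does and does not emulate

The generator stands in for a measured cross-section library, treatment
head simulation and phantom definition. It preserves: the Z and energy
scaling of the interaction channels, the pair threshold, the mixture rule,
the FFF/FF and 6/10 MV spectral orderings, and the study grid (five
materials × five concentrations × four beams in a 20 cm slab phantom). It
does not emulate: absorption edges, bound-electron corrections, true
TrueBeam spectral shapes, detector energy response or image formation.
Passing tests therefore demonstrate the structure of the contrast
physics — orderings, monotonicity, rate/endpoint consistency and
scaled-down magnitudes — not dosimetric-grade absolute prediction for real
beams.

## Numerical choices

- Spectrum bins: 200 log-spaced; analytic transmission evaluates bin
  midpoints; quadrature error is far below the model error.
- Empty phantoms transmit exactly 1; zero concentration returns the base
  material object unchanged (bitwise identity of the baseline).
- Interpolation tie-break: queries exactly on grid nodes return the
  tabulated value.
- The replica grid runs analytically by default (deterministic,
  sub-second); Monte Carlo grid runs are opt-in with per-cell histories.

## Known limitations

- **Iron oxide absolute scale.** With smooth power-law tables and a fixed
  geometry, every material's CE% carries a Compton floor proportional to
  the same C·x product. The frozen 14 cm tumour that brings the gold,
  platinum, iodine and silver maxima onto their reference scale leaves
  Fe₂O₃ at ≈ 3.9% where ≈ 1% is expected: the reference 19:1 Au:Fe₂O₃ span
  is wider than this parameterization can produce at any single geometry.
  The Fe₂O₃ maximum is reported as computed.
- The 6 MV FF versus 10 MV FF gap (~56% here) remains below the reference
  ~79%: with a shared Kramers shape, the 6/10 MV softness difference is
  carried almost entirely by the filter thicknesses, and pushing them
  further would break the FFF/FF ratios.
- Analytic and primary-only signals exclude scatter build-up; the scatter
  mode shows build-up raises absolute transmission substantially but
  affects the contrast ratios far less, which is why the analytic mode is
  the default analysis path.
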