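# Methods

## Droplet geometry

Each droplet of an adhered pair is modeled as a sphere truncated by one
plane; the two truncation planes coincide and the bilayer is the flat disc
of radius *r*c cut by that plane (area π*r*c²; the slight curvature of a
real contact patch is neglected). Volumes follow the spherical-cap formula
and are strictly increasing in *R* and decreasing in *r*c; the inverse map
(volume → radius at fixed *r*c) is solved with Brent's method on the
bracketing interval [*r*c, ∞). A full-sphere convention (ignoring the cap)
is provided as an alternative `geometry="sphere"` mode because published
droplet-pair analyses do not always state which convention they use. All
lengths are μm, areas μm², volumes μm³, matching permeabilities in μm/s.

## Osmotic transport and permeability estimation

State: volumes V₁, V₂; osmole contents n₁, n₂ (constant — the bilayer is
treated as solute-impermeable on the minutes timescale); contact area A
(constant = π·mean(*r*c)² by default, or per-frame interpolated); water
molar volume v_w = 1.8·10¹³ μm³/mol (18 cm³/mol; no temperature correction —
< 0.5% over the relevant range, temperature is metadata only).

dV₂/dt = *P*f A v_w (n₂/V₂ − n₁/V₁), dV₁/dt = −dV₂/dt.

The single ODE in V₂ (V₁ by conservation) is integrated with LSODA at
rtol 1e−10, which beats the analytic square-root-law oracle (n₁ = 0,
constant A) to better than 1e−6 relative everywhere it applies.

Osmolality (mOsm/kg, what a vapor-pressure osmometer reads) is treated as
numerically equal to osmolarity (mOsm/L) at these dilute (≤ 0.2 Osm)
concentrations. The default salty-droplet value for nominally 0.1 M NaCl
is 2 × 0.1 × φ with osmotic coefficient φ = 0.93, i.e. 0.186 Osm/L;
measured osmolalities can be passed instead.

**Estimation.** *P*f is fit by nonlinear least squares of the forward model
against the observed volumes of *both* droplets jointly (single-droplet
losses available). The initial volumes V₁(0), V₂(0) are co-estimated as
nuisance parameters: pinning them to the first observed frame would give a
single frame's measurement error a large lever arm on *P*f (an ~1.5% volume
error maps to ~10% in *P*f), whereas co-estimation leaves only the
frame-noise-averaged uncertainty (~1% per run at 0.5% radius noise).
Osmole contents stay fixed at the fitted initial volumes times the supplied
osmolarities. Runs are pooled as arithmetic mean ± sample SD (ddof = 1).

An independent initial-rate estimator divides the t = 0 slope of V₂
(quadratic fit over the first 10% of frames, read at t = 0 so the flux
decay from solute dilution does not bias it) by A(0)·v_w·Δc. It is exact
on noiseless data but has high variance on noisy single runs; it serves as
a cross-check and as the optimizer's starting point, not as the estimator.

## DSC analysis

Signals are molar excess heat capacity (kcal mol⁻¹ °C⁻¹); raw heat flow in
mW is converted via Cp = P/(β·n) given the scan rate β and moles of lipid.
Cooling scans (descending grids) are normalized ascending with the
direction retained as metadata. Endotherms are positive after baseline
correction regardless of plot orientation.

* Baseline: straight line fitted through user-specified flat pre-/post-
  transition windows (defaults −40…−32 and −4…0 °C), subtracted.
* *T*m: global maximum of the corrected signal, refined by 3-point
  parabolic interpolation; ties resolve to the lower temperature.
* ΔH: trapezoidal integral over the analysis window (default −30…−5 °C,
  appropriate for transitions in the −27…−17 °C range handled here).
* Deconvolution: nonlinear least squares (lmfit) of k ∈ {1, 2} Gaussian
  components in temperature; a pseudo-Voigt line shape is exposed as an
  option. Component areas are the Gaussian amplitude parameters, relative
  areas are percentages of their sum, and components are reported in
  descending-*T*m order (additive-poor first). Automatic k=2 starts try
  (apex, apex−2 °C), the mirrored (apex, apex+2 °C), and a start at the
  largest one-component residual, keeping the lowest-SSR fit — robust to
  the minor component sitting on either side of the apex.
* Model order "auto" compares AIC between k=1 and k=2 but accepts the
  two-component model only if its components are resolvably distinct
  (centers ≥ 0.5 °C apart, neither degenerate); on a noisy single
  transition two coincident Gaussians otherwise win the AIC without
  describing a real second domain.

**Identifiability.** Two Gaussians separated by much less than their widths
form a single smooth envelope; no fitting method can then localize the
centers to 0.1 °C at percent-level noise. The recovery test suite therefore
draws component separations of at least 2.5× the wider σ — a condition all
of the tabulated two-component presets satisfy comfortably.

## FTIR analysis

Spectra are assumed water-background-subtracted upstream; no ATR
penetration-depth correction is applied. Normalization divides by the
maximum in a reference window (by convention the ~2920 cm⁻¹ CH₂
antisymmetric stretch); it is idempotent and cancels arbitrary scaling.

* Position: apex grid point refined by 3-point parabolic interpolation
  (≤ 0.1 cm⁻¹ error for noiseless bands on the 4 cm⁻¹ grid); an
  intensity-weighted centroid above 80% height, evaluated on a 20×
  spline-upsampled profile, is available as an alternative. The estimator
  choice is recorded in shift-table metadata.
* FWHM: the windowed points are fitted with a pseudo-Voigt profile and the
  two half-maximum crossings are root-solved on the fitted curve. Direct
  interpolation of the raw samples (linear or spline) was rejected: on a
  4 cm⁻¹ grid it underestimates a sharp apex by several percent (e.g.
  +0.8 cm⁻¹ bias for a Lorentzian of FWHM 10) — the profile fit is exact
  across the Gaussian–Lorentzian family. Half-maximum is taken relative to
  zero by default; a local-minimum baseline mode exists for offset spectra
  but biases widths low when the window clips the band tails.
* Shift tables report Δν = position(sample) − position(control) with a
  ±0.5 cm⁻¹ dead band separating "red"/"blue" from "none".
* Default windows: νas CH₂ 2900–2940, νs CH₂ 2840–2870, νas PO₂⁻
  1200–1260 cm⁻¹. The ester C=O envelope (1700–1770 cm⁻¹) is defined but
  not analyzed by default — it is a broad multi-component band that a
  single-band position/FWHM reading would misrepresent.

## Trend classification

Mole ratios L:C convert to mole percent 100·C/(L+C); the control (1:0) is
the 0 mol % point. Percent change is 100·(sample − control)/control.
The response classifier is descriptive, not inferential: with tolerance τ
(default: pooled y_sd when dispersions are given, else 1% of the control
response) a series is *flat* if its total range fits within τ; *monotonic*
if all above-tolerance successive steps share a sign (so a decreasing
series that levels off still classifies monotonic-decreasing); *biphasic*
if the global interior extremum has an above-tolerance fall before and
rise after it (or mirrored); anything else is reported *complex*.

## Synthetic data

The generators emulate the study conditions: droplet pairs of 50 μm radius
with a 25 μm contact radius, osmolarities 0 vs 0.186 Osm/L, 300 s at 1 Hz;
thermograms on −40…0 °C at 0.05 °C sampling; spectra on 400–4000 cm⁻¹ at
4 cm⁻¹. Noise models are the simplest consistent with the instruments:
multiplicative Gaussian on radii (default SD 0.5% — imaging error scales
with droplet size; chosen so that recovery dispersion is comparable to
published permeability error bars), additive Gaussian on thermogram and
spectrum signals (default 0, set explicitly per experiment). All
randomness flows through explicit integer seeds; identical scenario + seed
is bit-identical. Every generator returns a ground-truth record alongside
the data so recovery tests never transcribe values by hand.

Preset registries encode the published condition values: permeabilities
74/72/68/74/78/82 μm/s across the DOPC series and 70 μm/s for the
DOPC/cholesterol control; the *T*m/ΔH table including the two-component
splits (second-peak centers and relative areas; component σ = 1.0 °C
adopted, since widths are not published); CH₂ bandwidths 21.67/23.35 cm⁻¹
(DOPC) and 24.27/24.09 cm⁻¹ (DOPC/Chol); and a PO₂⁻ shift series (0, −2,
−4, −6, −3, +1 cm⁻¹ around a 1230 cm⁻¹ control) following the reported
shift magnitudes, absolute published wavenumbers being unavailable.

**What passing recovery tests do and do not show.** They demonstrate the
estimators are unbiased and precise when the data-generating process
matches the model (Gaussian components, pseudo-Voigt bands, ideal osmotic
flux with impermeable solute, white observation noise). Real recordings
add effects the generators omit — contact-area drift, droplet
evaporation/coalescence, instrument baseline drift, correlated noise,
non-Voigt band shapes — so recovery on synthetic data bounds method error,
not total experimental error.

## Problem sizes

Default analyses run in seconds: a permeability fit handles 301 frames ×
2 droplets with a three-parameter optimization (tens of ODE solves);
recovery suites use 20 runs per condition, matching the n ≥ 20 averaging
convention for droplet experiments; thermogram fits use 801-point grids
and spectra 901-point grids.

## Known limitations

* Bilayer electrical properties, lipid exchange, solute permeation and
  non-planar contact mechanics are out of scope.
* The deconvolution line shape is a modeling choice; instrument software
  may use different shapes/constraints, so absolute component areas from
  real thermograms are convention-dependent even when synthetic recovery
  is exact.
* The biphasic classifier performs no hypothesis test; with large scatter
  and small effects its output depends on the tolerance choice.
* Vendor instrument formats (binary DSC/FTIR files, JCAMP-DX) are not
  parsed; inputs are plain CSV with fixed headers.
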