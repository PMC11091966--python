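# dibperm

Analysis toolkit for quantifying how a membrane-active additive (e.g. a
polyphenol such as curcumin) changes the physical state of phospholipid
model membranes, combining three instrument pipelines:

1. **Osmotic water permeability from droplet-interface bilayers (DIB).**
   Two lipid-monolayer-coated aqueous microdroplets (~100 μm diameter, one
   pure water, one ~0.1 M NaCl ≈ 0.186 Osm/L) adhere in oil and form a
   bilayer at their contact disc. Water flows toward the saltier droplet;
   filming the droplet radii for ~5 min and inverting the flux model yields
   the osmotic permeability coefficient *P*f (μm/s).
2. **DSC thermogram analysis.** Baseline correction, apex transition
   temperature *T*m, calorimetric enthalpy ΔH, and two-component Gaussian
   deconvolution of split transitions into additive-rich (lower *T*m) and
   additive-poor (higher *T*m) domains.
3. **ATR-FTIR band analysis.** Sub-resolution band positions and FWHMs of
   the CH₂ stretching (~2850/2920 cm⁻¹) and PO₂⁻ antisymmetric stretching
   (~1200–1260 cm⁻¹) bands on a 4 cm⁻¹ instrument grid, and red/blue shift
   tables across an additive concentration series.

A trend module converts lipid:additive mole ratios to mole percent and
classifies concentration responses (flat / monotonic / biphasic with an
interior extremum), and a synthetic-data module generates droplet series,
thermograms and spectra with known ground truth so that every estimator is
validated by parameter recovery.

## The core model

Each droplet is a truncated sphere (radius *R*, contact-disc radius *r*c),

V = (4/3)πR³ − πh²(3R − h)/3,  h = R − √(R² − r*c*²),

and the water flux across the bilayer disc *A* = π r*c*² obeys

dV₂/dt = *P*f · A · v_w · (c₂ − c₁),  c_i = n_i / V_i,  dV₁/dt = −dV₂/dt,

with v_w = 1.8·10¹³ μm³/mol the molar volume of water and n_i the (constant)
osmole contents. For a pure-water partner droplet and constant area the
trajectory follows V₂(t)² = V₂(0)² + 2 *P*f A v_w n₂ t, which serves as the
analytic oracle for the ODE integrator. *P*f is estimated per recording by
nonlinear least squares of this forward model against the observed volumes
of both droplets (initial volumes co-estimated; runs pooled as mean ± SD).

## Worked example

Generate one noisy droplet-pair recording at the 50:1 lipid:curcumin
condition (ground truth *P*f = 68 μm/s) and re-estimate the permeability:

```sh
$ dibperm synth dib --preset dopc_50to1 --seed 11 --out demo
$ dibperm fit-pf demo/series.csv --osm1 0 --osm2 0.186
{
 "pf_hat": 67.3040232247299,
 "residual_rms": 7786.540210166465,
 "initial_rate_pf": 43.089830663232775,
 ...
}
```

A single 0.5%-radius-noise run lands within ~1% of the generating value
(67.3 vs 68 μm/s); averaging 20 runs recovers it to a few tenths of a
percent. (`initial_rate_pf` is a rough slope-based cross-check; it is noisy
on single runs and only meant to flag gross model misfits.)

Deconvolving a synthetic thermogram generated at the high-curcumin (4:1)
calorimetry condition:

```sh
$ dibperm synth dsc --preset dopc_4to1 --out demo_dsc
$ dibperm dsc-fit demo_dsc/thermogram.csv --k 2
{
 "tm_apex_C": -22.21231515367386,
 "dh_kcal_per_mol": 6.239999999999955,
 "k": 2,
 "components": [
  {"tm": -20.300000000001493, "rel_area": 18.000000000026127, ...},
  {"tm": -22.280000000000353, "rel_area": 81.99999999997387, ...}
 ]
}
```

The fit recovers the generating parameters: total enthalpy 6.24 kcal/mol
and an 82% lower-temperature (additive-rich) component at −22.28 °C beside
an 18% component at −20.30 °C.

Other subcommands: `simulate-dib` (noiseless forward simulation),
`ftir-bands` (band-shift table from labelled spectra), `classify`
(concentration-response shape). `--help` on any subcommand lists flags; a
YAML `--config` file can hold per-subcommand defaults.

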