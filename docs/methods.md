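# Methods

## Scope and model structure

`canopyflux` couples three submodels, each exchanging quantities on a
fixed spectral grid of 60 half-open 5-nm bands covering PAR
([400, 700) nm).  A spectrum value is the band-integrated photon flux
(µmol m⁻² s⁻¹ per band), never a density, so totals are exact sums.

1. **Canopy geometry.** Each plant is a vertical stem of phytomers in
   137.5° spiral phyllotaxy.  A composite leaf is a straight rachis
   leaving the stem at the leaf insertion angle (LIA, measured from the
   stem axis) and pitched by the rachis angle (RA), carrying 7 leaflet
   pairs plus a terminal leaflet (15 leaflets).  Leaflets are planar
   ellipses (fan-triangulated, 16 triangles each by default) in three
   groups — basal, middle, outer — whose elevation angles, like the
   terminal-leaflet angle (TLA), are applied *relative to the rachis
   axis*, so tilting the leaf tilts its leaflets.  Leaflet linear size is
   proportional to √(leaf length × leaf width), with relative sizes
   0.55 / 0.75 / 0.85 / 1.0 for basal / middle / outer / terminal
   leaflets; summed leaflet area is therefore proportional to
   length × width, the standard ellipse-sum leaf-area model.  Leaf size
   declines toward the apex with an age multiplier rising linearly from
   0.3 (rank 1, youngest) to 1.0 at rank 6.
2. **Light transport.** A forward Monte Carlo path tracer samples ray
   origins along LED line lamps and directions from a discretized
   hemispheric emission pattern (10° polar bins, azimuthally symmetric).
   Each ray carries the source band spectrum as a weight vector.  At a
   surface hit, the per-band absorbed fraction `a(b) = 1 − R(b) − T(b)`
   is tallied to that leaflet and the surviving weight is attenuated by
   `R(b) + T(b)`; the ray then reflects or transmits (one geometric
   decision, importance-weighted across bands so every band remains
   unbiased) with a cosine-weighted Lambertian direction on the chosen
   side.  Mirror walls on the four box sides are handled analytically
   (lossless specular reflection), the floor absorbs, and the open top
   tallies escape.  Paths are capped at 40 scattering recursions;
   remaining weight is reported as truncated, never dropped, so the
   per-band balance absorbed + floor + stems + escaped + truncated =
   emitted holds to floating-point rounding on every run.
3. **Leaf physiology.** Per-leaflet absorbed spectra (converted to per
   m² leaf) drive a non-rectangular hyperbola
   θP² − (αI + P_max)P + αI·P_max = 0 (smaller root) with
   αI = Σ_b α(b)·A(b).  P_max(rank) = J_max,top × age(rank) × c_CO₂,
   where the fixed factor c_CO₂ = 0.18 is the electron-transport-limited
   conversion (C_i − Γ*)/(4C_i + 8Γ*) evaluated at 500 ppm ambient CO₂
   (C_i ≈ 0.7 × 500 ppm) and 22 °C (Γ* ≈ 40 ppm).  The module returns
   gross photosynthesis; respiration, stomatal conductance and
   transpiration are out of scope.  Temperature hooks exist but are
   inert at the fixed 22 °C default.

A scenario couples a *growth* color — fixing architecture, leaf optics
and the quantum-efficiency context — with an *exposure* color — fixing
the lamp spectrum — at one of three scales: a single mature leaf in a
1 × 1 m mirrored box under a short LED string, 32 seven-leaf young
plants, or 32 twenty-one-leaf plants (crop).  Crop-scale results
aggregate leaflet photosynthesis to µmol CO₂ per m² floor; light-use
efficiency is LUE = P / (absorbed/1000), and the identity
LUE × absorbed(mmol) = P holds to machine precision by construction.

## Scene and source parameters

| parameter | default | note |
|---|---|---|
| floor | 3.2 × 3.0 m | 32 plants, two double rows (x = 0.6/1.0 and 2.2/2.6 m), 8 plants per row |
| slab height | 0.8 m | plant bases |
| plant tops | 3.5 m | 21 internodes of 0.1286 m |
| lamps | 2 line sources, 2.5 m long, 4.75 m high | one above each double row, cosine pattern |
| source flux | 100 µmol m⁻² ground s⁻¹ | per color |
| LED peaks | 446 / 530 / 627 / 663 nm | Gaussian, FWHM 25 nm, truncated to PAR and renormalized |
| white spectrum | 13 % blue / 55 % green / 32 % red | uniform within each 100-nm region |
| LAI target | 3.0 | leaflet sizes rescaled globally, calibrated on the white-grown crop |
| stems/trusses | R = 0.15, T = 0 | absorbing gray cylinders (radius 7 mm stem, 8 trusses per crop plant); intercept but do not photosynthesize |

The lamp's angular table is a documented stand-in (cosine-weighted lower
hemisphere in 10° bins); a measured 9-bin pattern can be passed instead.
The leaflet size multiplier calibrated on the white-grown crop is applied
unchanged to all treatments, so measured per-treatment leaf dimensions
translate directly into per-treatment LAI (e.g. the small blue-grown
leaves give LAI ≈ 1.9, green-grown ≈ 3.3).

## Physiological parameters

* α (quantum efficiency, µmol CO₂ µmol⁻¹ *absorbed* photons) defaults to
  0.055 / 0.065 / 0.075 for blue / green / red bands, piecewise constant
  over the 100-nm color regions.  The ordering follows the classical
  action spectrum; the absolute level places leaf LUE near 60–70 µmol
  CO₂ mmol⁻¹ at moderate light, the range typical for young tomato
  leaves.  α is never hard-coded: it lives in `data/defaults.yaml` and
  can be re-estimated from gas-exchange data with `calibrate_alpha`
  (bounded least squares on the hyperbola; raises when all measurements
  are light-saturated, where α is unidentifiable).
* The growth-color context multiplies α by 0.85 / 1.05 / 0.95 / 1.0 for
  blue / green / red / white-grown leaves.  This emulates the measured
  pattern that leaves developed under blue light fix the least CO₂ per
  absorbed photon under their growth light while green-grown canopies
  utilize light best; the multipliers are a calibration context, chosen
  once, not a fitted quantity.
* J_max,top = 150 µmol electrons m⁻² s⁻¹, θ = 0.7, age decline 3 % per
  rank with a floor of 0.45 — standard values for indeterminate
  greenhouse tomato.

## Synthetic data

The generators produce every pipeline input with the qualitative
structure of the measurements they emulate:

* **Architecture:** the measured per-treatment means (leaf length/width,
  LIA, RA, TLA, basal/middle/outer angles) with optional replicate noise
  (lognormal on lengths, truncated Gaussian on angles).
* **Leaf optics:** absorptance 0.93 minus a Gaussian green dip at 550 nm
  (deeper for green-grown leaves) plus a small 450-nm carotenoid boost;
  the non-absorbed remainder splits 55/45 between reflectance and
  transmittance with treatment offsets enforcing the measured orderings
  (green-grown: highest transmission everywhere; blue-grown: highest
  reflection except near 550 nm).  White-light-weighted absorption
  fractions land in 0.85–0.92 for all treatments.
* **Gas exchange:** gross P forward-modeled through the hyperbola at
  stated absorbed irradiances with multiplicative lognormal noise;
  ground truth is stored alongside for recovery tests.

What passing tests therefore show: the *mechanisms* — spectral
bookkeeping, geometry, transport, physiology and their coupling — behave
correctly, and the qualitative response patterns (green light least
absorbed at every scale; color contrasts shrinking from leaf to crop;
green-grown > red-grown > blue-grown crop absorbance; maximum LUE for
green-grown crops under red light) emerge from those mechanisms.  They
do not validate absolute absorbance or photosynthesis levels against a
real crop: the leaflet arrangement, lamp pattern and α levels are
stand-ins, and the simulated absolute values (e.g. crop absorbance near
80 % rather than 90 %) reflect that stand-in geometry.

## Numerical choices

* Ray acceleration: uniform voxel grid (~2 cells per triangle, capped at
  192 per axis) traversed by 3-DDA; intersection by Möller–Trumbore with
  a 10⁻⁹ m minimum hit distance and 10⁻⁶ m normal offset after
  scattering to avoid self-intersection.
* RNG: one splitmix64-seeded xorshift64* stream per ray, so runs are
  bit-reproducible for a given seed independent of batching; ray
  origins/directions use a PCG64 generator with the same seed.  The
  default public seed is 20140901.  Scenario batches share one seed
  (common random numbers), which pairs the color comparisons and
  resolves small absorbance contrasts at moderate ray counts.
* Wall bounces are capped at 1000 per path (near-horizontal rays);
  capped weight is tallied as truncated.
* Desk-scale default is 2×10⁵ rays per scenario (Monte Carlo standard
  error of crop absorbance ≈ 0.07 percentage points, measured by batch
  replication); the production-scale 2×10⁷ rays is a config change.
  Acceptance-style pattern tests use 1–4 × 10⁵ rays so the full suite
  runs in minutes.
* Geometry poking through a mirror wall is folded back per triangle
  (reflected about the wall plane), which is optically equivalent in the
  mirrored system; the mirror-equivalence test checks the box against an
  explicitly unfolded 3×3 tiling.
* Per-leaflet gross P is a concave function of noisy Monte Carlo fluxes,
  so very low ray counts bias aggregate P slightly downward; at the
  desk-scale defaults (≥ 20 rays per leaflet) the effect is at the
  percent level and shrinks with ray count.

## Known limitations

* The crop is static: no growth, organogenesis or dynamic spectral
  response; treatment effects enter only through the end-state
  parameters.
* Leaflet outlines, their arrangement along the rachis and leaf
  curvature are an idealization (three-group elevation angles, straight
  rachis); the real curvature function of the underlying cultivar
  parameterization is not public.
* No solar/diffuse background, no far-red, no fluorescence or energy
  balance; the scene is LED-only PAR transport.
* Optical properties are empirical inputs per treatment; there is no
  pigment-to-optics model, and adaxial/abaxial optics default to
  symmetric.
* Stems and trusses intercept (≈ 5 % of input at crop scale) but do not
  photosynthesize, and greenhouse hardware (wires, slabs, gutters) is
  not modeled.
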