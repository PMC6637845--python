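# canopyflux

A multispectral functional-structural plant model (FSPM) for greenhouse
tomato: an explicit 3D canopy, band-wise Monte Carlo light transport, and
spectrum-dependent leaf photosynthesis, built to quantify how the *color*
of light shapes crop performance through two distinct routes —

1. **growth-light color** changes plant architecture (leaf size, insertion
   and rachis angles) and leaf optics (reflectance/transmittance spectra),
   which set how much light the canopy intercepts; and
2. **exposure-light color** changes the quantum efficiency of
   photosynthesis per absorbed photon (the action spectrum: red > green >
   blue).

The package is aimed at crop physiologists and horticultural-lighting
researchers who want to upscale leaf-level spectral measurements to
whole-canopy light absorbance, gross photosynthesis and light-use
efficiency.

## Model

All spectra live on a fixed grid of 60 five-nm bands over PAR
(400–700 nm).  Leaf absorptance is `a(λ) = 1 − R(λ) − T(λ)`.  A Monte
Carlo path tracer launches rays from LED line lamps (discretized 10°
emission pattern) through a triangulated canopy of 32 plants × 21
composite leaves × 15 elliptical leaflets inside a mirrored box
(infinite-canopy boundary); each ray carries the full band spectrum as a
weight vector attenuated at every Lambertian scattering event, so photon
conservation per band is exact.  Per-leaflet absorbed spectra drive a
non-rectangular hyperbola

```
θ·P² − (αI + P_max)·P + αI·P_max = 0,    αI = Σ_b α(b)·A(b)
```

with an age-dependent `P_max` derived from J_max, yielding gross
photosynthesis per m² floor and light-use efficiency
LUE = P / (absorbed / 1000) in µmol CO₂ mmol⁻¹ absorbed light.

Synthetic generators supply every input with the measured qualitative
structure (per-treatment architecture table, 550-nm-peaked leaf optics,
LED/white source spectra, gas-exchange calibration data), so the whole
pipeline runs and is tested without external data.

## Worked example

A crop grown under green light (tall open architecture, high-transmission
leaves) transferred to red LED light — the most efficient pairing:

```python
from canopyflux import ScenarioConfig, ScenarioSpec, run_scenario

cfg = ScenarioConfig()
spec = ScenarioSpec(grown_under="green", exposed_to="red", scale="crop",
                    n_rays=200_000, seed=42)
res = run_scenario(spec, cfg)
print(f"LAI: {res.lai:.2f}")
print(f"absorbance: {res.absorbance_pct:.1f}% of input")
print(f"gross photosynthesis: {res.gross_P:.2f} umol CO2 m-2 floor s-1")
print(f"light-use efficiency: {res.lue:.1f} umol CO2 mmol-1 absorbed")
```

prints

```
LAI: 3.33
absorbance: 82.5% of input
gross photosynthesis: 6.16 umol CO2 m-2 floor s-1
light-use efficiency: 74.7 umol CO2 mmol-1 absorbed
```

The crop absorbs 82.5% of the 100 µmol m⁻² s⁻¹ red input (green-grown
plants have the largest leaf area, hence the highest interception of the
three colored-grown crops), and each mmol of absorbed red photons fixes
74.7 µmol CO₂ — the maximum cell of the 3×3 growth-color × exposure-color
matrix, because red photons carry the highest quantum efficiency while
the green-grown canopy spreads the light over the most leaf area.

The same engine is scriptable from the shell:

```bash
canopyflux synth --seed 1 --out fixtures/         # write all synthetic inputs
canopyflux trace --grown white --scale crop --source red --rays 200000 --out tally.csv
canopyflux scenarios run --preset paper18 --rays 200000 --seed 1 --out results/
```

## Layout

```
src/canopyflux/
  spectra.py       band grid, leaf optics, LED/white source spectra
  architecture.py  per-treatment plant-architecture parameter sets
  geometry.py      3D leaf/plant/scene construction, OBJ export
  transport.py     Monte Carlo light transport (numba kernel in _kernel.py)
  physiology.py    leaf photosynthesis, α calibration, LUE
  scenarios.py     scenario matrix orchestration
  synthetic.py     synthetic input generators
  cli.py           command-line interface
docs/methods.md    model description, parameter choices, limitations
```
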