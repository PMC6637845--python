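# Default model configuration.
#
# alpha: quantum efficiency (µmol CO2 per µmol absorbed photons) by color
# region of the exposure spectrum: blue 400–500 nm, green 500–600 nm,
# red 600–700 nm.  Values follow the classical action-spectrum ordering
# (red > green > blue) and sit in the range typical for tomato leaves;
# they can be recalibrated from gas-exchange data with calibrate_alpha.
photosynthesis:
  alpha:
    blue: 0.055
    green: 0.065
    red: 0.075
  # growth-spectrum context: multiplier on alpha for leaves developed under
  # each growth color (emulating the measured growth-light effect on leaf
  # quantum efficiency: lowest for blue-grown, highest for green-grown).
  alpha_growth_multiplier:
    white: 1.00
    blue: 0.85
    green: 1.05
    red: 0.95
    amber: 1.00
    redblue: 0.95
  j_max_top: 150.0          # µmol electrons m-2 s-1 for young fully expanded leaves
  theta: 0.7                # curvature of the non-rectangular hyperbola
  co2_factor: 0.18          # electron-transport-to-CO2 factor at 500 ppm / 22 C
  age_decline_per_rank: 0.03  # J_max multiplier drops by this per rank from the top
  age_decline_floor: 0.45
  temperature_C: 22.0
  co2_ppm: 500.0

led:
  peaks_nm:
    blue: 446.0
    green: 530.0
    amber: 627.0
    red: 663.0
  fwhm_nm: 25.0

source:
  total_flux: 100.0         # µmol m-2 ground s-1 per color
  pattern: cosine

trace:
  n_rays: 200000
  max_recursions: 40
  seed: 20140901
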