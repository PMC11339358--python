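# Synthetic engineered-pupil geometry (crossed opaque-bar design).
#
# This is a package-designed stand-in for a structured illumination mask,
# chosen to meet the published design targets of the technique: it keeps
# ~1/3 of the beam photons, redistributes PSD energy into eight strong
# sidelobes with different x and y peak radii, and places the 2nd-order
# x sidelobe of a 106-180 um powder autocorrelation at 0.055.
# Vertical bars: period 1.4 mm, open duty 0.399; horizontal bars:
# period 1.8 mm, open duty 0.8354; all features mm-scale.
aperture_diameter_mm: 5.0
primitives:
- shape: rect
  cx_mm: -2.1
  cy_mm: 0.0
  w_mm: 0.8414
  h_mm: 6.0
  transmission: 0
- shape: rect
  cx_mm: -0.7
  cy_mm: 0.0
  w_mm: 0.8414
  h_mm: 6.0
  transmission: 0
- shape: rect
  cx_mm: 0.7
  cy_mm: 0.0
  w_mm: 0.8414
  h_mm: 6.0
  transmission: 0
- shape: rect
  cx_mm: 2.1
  cy_mm: 0.0
  w_mm: 0.8414
  h_mm: 6.0
  transmission: 0
- shape: rect
  cx_mm: 0.0
  cy_mm: -0.9
  w_mm: 6.0
  h_mm: 0.296241
  transmission: 0
- shape: rect
  cx_mm: 0.0
  cy_mm: 0.9
  w_mm: 6.0
  h_mm: 0.296241
  transmission: 0
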