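name: ACR
n_slices: 3
signal_region:
  shape: circle
  radius: 95.0
analysis_slices:
  geometry: 2
  resolution: 0
  ramps: 0
  wedges: 0
  uniformity: 2
zones:
- zone_id: 1
  center:
  - 0.0
  - 0.0
  label: center
paths:
- path_id: horizontal
  kind: edge
  nominal_mm: 190.0
  angle_deg: 0.0
- path_id: vertical
  kind: edge
  nominal_mm: 190.0
  angle_deg: 90.0
- path_id: diag_BL_TR
  kind: edge
  nominal_mm: 190.0
  angle_deg: 45.0
- path_id: diag_BR_TL
  kind: edge
  nominal_mm: 190.0
  angle_deg: 135.0
structures:
- kind: ramp_pair
  id: ramp_acr
  zone_id: 1
  slice_index: 0
  geometry:
    center:
    - 0.0
    - -16.0
    axis: x
    extent_mm: 90.0
    strip_width_mm: 4.0
    strip_sep_mm: 8.0
    slope_ratio: 10.0
    low_level: 0.12
- kind: wedge_pair
  id: wedge_acr
  zone_id: 1
  slice_index: 0
  geometry:
    center:
    - 0.0
    - 55.0
    bar_offset_mm: 6.0
    bar_width_mm: 3.0
    base_length_mm: 20.0
- kind: hole_array
  id: holes_1p1
  zone_id: 1
  slice_index: 0
  geometry:
    center:
    - -27.0
    - -45.0
    size:
    - 24.0
    - 24.0
    pitch_mm: 1.1
    n: 6
    hole_diameter_mm: 0.55
    ref_hole_offset:
    - -8.0
    - 8.0
    ref_hole_diameter_mm: 4.0
    background_level: 0.1
- kind: hole_array
  id: holes_1p0
  zone_id: 1
  slice_index: 0
  geometry:
    center:
    - 0.0
    - -45.0
    size:
    - 24.0
    - 24.0
    pitch_mm: 1.0
    n: 6
    hole_diameter_mm: 0.5
    ref_hole_offset:
    - -8.0
    - 8.0
    ref_hole_diameter_mm: 4.0
    background_level: 0.1
- kind: hole_array
  id: holes_0p9
  zone_id: 1
  slice_index: 0
  geometry:
    center:
    - 27.0
    - -45.0
    size:
    - 24.0
    - 24.0
    pitch_mm: 0.9
    n: 6
    hole_diameter_mm: 0.45
    ref_hole_offset:
    - -8.0
    - 8.0
    ref_hole_diameter_mm: 4.0
    background_level: 0.1
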