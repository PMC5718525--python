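# Three-shot plug plan fixture for the 16 cm spherical gel phantom.
# Shot positions, collimators and plug counts follow the study plan summary;
# the wedge azimuths are a synthetic stand-in for the unrecorded plug
# positions: each shot's wedge spans 360 deg x (plugs used / 201 sources),
# facing the organ-at-risk side, with 0.2 residual transmission for dose
# reaching the sector from unplugged beams.
prescription_dose_gy: 8.0
prescription_isodose: 0.5
phantom_radius_mm: 80.0
phantom_center_mm: [100.0, 100.0, 100.0]
shots:
- isocenter_mm: [102.0, 84.0, 103.0]
  collimator_mm: 18.0
  weight: 1.0
  plug_sectors:   # 45 of 201 plugs -> 80.6 deg wedge toward +X
  - {azimuth_start_deg: 319.7, azimuth_end_deg: 40.3, transmission: 0.2}
- isocenter_mm: [101.0, 110.0, 101.0]
  collimator_mm: 14.0
  weight: 1.0
  plug_sectors:   # 21 of 201 plugs -> 37.6 deg wedge toward +X
  - {azimuth_start_deg: 341.2, azimuth_end_deg: 18.8, transmission: 0.2}
- isocenter_mm: [76.0, 95.5, 106.5]
  collimator_mm: 8.0
  weight: 1.0
  plug_sectors:   # 46 of 201 plugs -> 82.4 deg wedge toward -X
  - {azimuth_start_deg: 138.8, azimuth_end_deg: 221.2, transmission: 0.2}
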