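# Nominal illumination train of the sample-scanning light-sheet design.
# 2 mm collimated 488 nm input; resonant galvo + fold mirror; f=30/f=80
# beam-expanding telescope; rectangular slit (width is the free calibration
# parameter, see lsfmkit.optics.calibrate_aperture); f=75 cylindrical lens
# (power on the sheet-thin axis); f=250 relay whose back focal plane holds
# the pupil of the 20x (f = 200/20 = 10 mm) NA 0.6 illumination objective.
# Positions are along the unfolded optical axis in mm.
input_beam_diameter_mm: 2.0
wavelength_nm: 488.0
immersion_index: 1.333
elements:
  - {kind: fold-mirror, axial_position_mm: 0.0, clear_half_aperture_mm: 5.0, label: resonant-galvo}
  - {kind: fold-mirror, axial_position_mm: 15.0, clear_half_aperture_mm: 12.5, label: fold-mirror}
  - {kind: thin-lens, axial_position_mm: 30.0, focal_length_thin_mm: 30.0, focal_length_wide_mm: 30.0, clear_half_aperture_mm: 12.5, label: L1}
  - {kind: thin-lens, axial_position_mm: 140.0, focal_length_thin_mm: 80.0, focal_length_wide_mm: 80.0, clear_half_aperture_mm: 12.5, label: L2}
  - {kind: aperture, axial_position_mm: 220.0, clear_half_aperture_mm: 1.0, label: rectangular-slit}
  - {kind: cylindrical-lens, axial_position_mm: 250.0, focal_length_thin_mm: 75.0, clear_half_aperture_mm: 12.5, label: L3}
  - {kind: thin-lens, axial_position_mm: 575.0, focal_length_thin_mm: 250.0, focal_length_wide_mm: 250.0, clear_half_aperture_mm: 25.0, label: L4}
  - {kind: objective, axial_position_mm: 825.0, focal_length_thin_mm: 10.0, focal_length_wide_mm: 10.0, numerical_aperture: 0.6, clear_half_aperture_mm: 10.0, label: illumination-objective}
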