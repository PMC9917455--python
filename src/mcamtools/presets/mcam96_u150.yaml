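# 96-camera array at the nominal 150 mm working distance (long-axis overlap ~37%,
# short axis has a small coverage gap under the thin-lens model)
camera:
  focal_length_mm: 25.0
  numerical_aperture: 0.03
  pixel_pitch_um: 1.4
  sensor_px: [4320, 2432]
  wavelength_um: 0.5
grid: [8, 12]
pitch_mm: 19.0
working_distance_mm: 150.0
long_axis: grid_x
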