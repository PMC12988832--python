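# Demo run config for `pavis run --config examples/demo_config.yaml --out demo/`
# (equivalent to the built-in default demo configuration)
output_dir: demo
seed: 1
acquisition:
  n_elements: 128
  aperture_width_mm: 11.52
  n_samples: 832
scene:
  lumen:
    center: [-2.0, 4.5]        # lateral, depth (mm)
    half_widths: [2.2, 0.9]    # lateral, axial (mm)
    shape: ellipse
    n_absorbers: 80
    amplitude: 1.0
  adventitia:
    n_absorbers: 10
    amplitude: 0.6
    thickness_mm: 0.15
  noise_sigma: 0.12
time_points:
  - {minutes: 10, n_frames: 5, amplitude: 0.3, n_duplicates: 1, n_miss: 1}
  - {minutes: 20, n_frames: 5, amplitude: 1.0, n_duplicates: 1, n_miss: 1}
  - {minutes: 30, n_frames: 5, amplitude: 0.8, n_duplicates: 1, n_miss: 1}
  - {minutes: 60, n_frames: 5, amplitude: 0.5, n_duplicates: 1, n_miss: 1}
  - {minutes: 70, n_frames: 5, amplitude: 0.3, n_duplicates: 1, n_miss: 1}
  - {minutes: 80, n_frames: 5, amplitude: 0.55, n_duplicates: 1, n_miss: 1}
beamform:
  dynamic_range_db: 30.0
  bandpass: false
roi:
  lateral_mm: 3.0
  axial_mm: 0.6
selection:
  iou_threshold: 0.95
  corr_threshold: 0.99
  min_overlap_px: 1
stats:
  adjust: none
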