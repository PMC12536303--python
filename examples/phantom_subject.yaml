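# Three-site synthetic subject: epithelium thins from the labia majora to
# the labia minora; every site carries two decorrelating vessels.  Distances
# in µm; vessel coordinates in (x, y, z) voxel indices.
subject_id: phantom-A
group: control
seed: 77

sites:
  labia_majora:
    phantom:
      n_positions: 32
      epithelium_thickness_um: 300.0
      vessels: &tubes
        - line: {start: [0, 8, 120], end: [127, 8, 120]}
          radius_um: 136.72
        - line: {start: [0, 22, 140], end: [127, 22, 140]}
          radius_um: 97.66
  interlabial_sulci:
    phantom:
      n_positions: 32
      epithelium_thickness_um: 200.0
      vessels: *tubes
  labia_minora:
    phantom:
      n_positions: 32
      epithelium_thickness_um: 120.0
      vessels: *tubes

angiography:
  window: 2              # lateral averaging half-width (5 A-lines)
  threshold_quantile: 0.25
  depth_range: null      # null = below the detected surface

vessels:
  scales_um: [195.0, 273.0]
  method: fixed          # width-accurate; the default "otsu" segments more
  fixed_threshold: 0.2   # conservatively and erodes vessel borders
  sample_step_px: 10

thickness:
  min_contrast: 0.3      # log-amplitude units
  group_index: 1.0       # 1.4 converts optical to geometric thickness

report:
  outdir: octamorph_out
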