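# Demo recipe: 20 synthetic cells with abundant cytoplasmic labelling,
# two biological repeats, short acquisition for speed.
seed: 7
simulate:
  n_cells: 20
  occupancy: 1.0
  emitters_per_cell: 40
  compartment: cytoplasm
  condition: demo
  n_repeats: 2
  cells_per_fov: 10
imaging:
  n_frames: 40
  photons_per_frame: 300
  bg_photons: 20
segment:
  min_area_um2: 0.5
  max_area_um2: 20.0
localize:
  noise_k: 5.0
traces:
  window: 12
  p: 2.0
  min_step_k: 3.0
  d_max_nm: 500.0
  max_gap: 1
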