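# Small end-to-end demo: simulate a 6x6 microwell grid for 5 minutes, segment
# and filter single live cells, extract the 169-column feature table, then run
# the classification protocol and the sub-phenotype clustering on the result.
seed: 7
out_dir: morphodyn_demo
scene:
  grid_rows: 6
  grid_cols: 6
  frames: 5
  dead_fraction: 0.1
segmentation: {}
extraction: {}
classify:
  repeats: 5
  n_components: 5
  n_rounds: 20
cluster:
  k_min: 2
  k_max: 5
  n_components: 5
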