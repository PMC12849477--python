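# A down-scaled scenario for quick end-to-end runs (~15 s).
# Omitted blocks fall back to the package defaults.
scenario:
  seed: 42
  timepoints: [2.0, 7.0, 20.0]
  fc_events: 20000
  fields_per_sample: 2
  geometry:
    width: 256
    height: 256
    n_cells: 40

stats:
  fc_subsample: 250
  microscopy_subsample: 150

kinetics:
  window_size: 3
  detection_limit: 1.0e-9
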