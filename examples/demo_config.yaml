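# Demo configuration: a small fully synthetic run exercising every stage.
synthetic:
  n_species: 400
  n_countries: 12
  n_families: 30
  seed: 7
synonym_rate: 0.15
hybrid_rate: 0.02
include_nt: false
stats:
  n_permutations: 199
grid:
  cell_size_deg: 0.7
out_dir: demo_out
overwrite: true
seed: 7
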