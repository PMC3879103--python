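name: scenario1
n_genotypes: 177
n_markers: 275
design:
  type: alpha
  n_blocks_per_rep: 10
  block_size: 18
  n_reps: 2
variance_components:
  marker: 0.2019
  block: 69.9089
  residual: 48.6728
n_datasets: 1000
seed: 20131486
cv: {k: 3, n_reps: 5}
markers: {maf_low: 0.05, maf_high: 0.5, missing_rate: 0.02, het_rate: 0.01}
missing_yield_rate: 0.0
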