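# Multi-trial scenario: 698 genotyped doubled-haploid lines in lattice-square
# trials of 10x10 with two replicates.  In the default genotyped-only mode the
# 698 lines occupy 7 trials (two surplus plots become checks); setting
# include_nongenotyped: true adds 202 non-genotyped lines (variance component
# `nongeno`) and expands the layout to 9 trials / 1800 plots.
name: scenario3
n_genotypes: 698
n_markers: 11646
design:
  type: lattice
  n_trials: 7
  lattice_dim: 10
  n_reps: 2
variance_components:
  marker: 0.005892
  trial: 11.8285
  trial_rep: 3.3231
  block: 6.3148
  nongeno: 34.5717
  residual: 53.8715
n_datasets: 1000
seed: 20133486
cv: {k: 3, n_reps: 5}
markers: {maf_low: 0.05, maf_high: 0.5, missing_rate: 0.02, het_rate: 0.01}
missing_yield_rate: 0.02111   # 38 of 1800 plots without yield
n_nongenotyped: 202
include_nongenotyped: false
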