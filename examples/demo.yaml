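# Demo cohort: 11 AD + 9 control donors x 3 regions x 100 cells/sample
# on a 3 x 20 Mb synthetic genome. All stage parameters at their defaults.
seed: 1
outdir: scratch/demo_run
stages: [simulate, methylome, states, contacts, genome3d, loops]
log_level: INFO
simulation:
  n_ad_donors: 11
  n_control_donors: 9
  cells_per_sample: 100
methylome:
  # coverage bounds scaled to the synthetic sequencing depth
  coverage_min: 1000
  coverage_max: 10000000
  top_k: 600
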