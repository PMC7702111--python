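# Demo configuration for `pond-assembly run --config examples/demo.yaml`.
# Scaled to finish in a few minutes on one CPU while exercising every stage.
seed: 7
out_dir: pond_demo
n_reads: 20000
n_genotypes: 10
min_genotype_distance: 5
error_model:
  pcr_error_rate: 1.0e-5
  pcr_cycles: 30
  seq_error_rate: 1.0e-3
  chimera_rate: 0.01
metacommunity:
  pool_size: 400
  individuals_per_site: 1000
rarefy_depth: 800
null_model:
  n_reps: 200
bnti_reps: 99
geochem_sites: 20
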