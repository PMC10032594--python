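# Demo configuration for `strhab run --config examples/demo_config.yaml`.
# Any omitted key falls back to the pipeline default; unknown keys are rejected.
seed: 5
cohort:
  n_accessions: 120
  n_subpops: 6
  n_str_loci: 60
  n_snps: 200
  n_env_vars: 30
retention_rule: "cumulative:0.8"
max_axes: 7
min_units: 4
mock_seeds: 2
prior_sd: 1.0
overlap_draws: 1000
run_lmm: false
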