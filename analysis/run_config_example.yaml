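# Example config for `ocdim run-all --config analysis/run_config_example.yaml`.
# Supply either a `sim` block (synthetic cohort) or `input_paths` with
# responses/domain_map/severity/flags CSVs, never both.
out_dir: results/run_all
seed: 7
sim:
  n_persons: 500
  seed: 0
quad_nodes: 21
quad_nodes_specific: 15
quad_nodes_per_dim: 4
fit_tol: 0.001
run_lodo: false
mcmc_iterations: 4000
mcmc_burn_in: 1000
mcmc_chains: 2
mcmc_person_thin: 5
psrf_threshold: 1.2
agreement_z: 1.96
log_level: INFO
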