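# Example run configuration for `ieegnet run-all --config docs/example_config.yaml`.
# A reduced synthetic cohort; drop the `cohort` block and supply `patients`
# (sensors_csv + edf or adjacency_csv per patient) for real-data mode.
seed: 42
measures: [beta_coherence]
cohort:
  n_ecog: 4
  n_seeg: 4
  duration: 120.0      # seconds per recording (default 300)
  fs: 256.0
window_s: 1.0
taper_nw: 2.0
taper_k: 3
louvain_runs: 100
louvain_gamma: 1.0
distance_starts: 20
compute_participation: true
write_recordings: false
output_dir: ieegnet_results
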