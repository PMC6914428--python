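# Example: synthetic cohort with a planted homotopic decline in the FPN.
seed: 7
simulate:
  n_subjects: 60
  networks: {SMN: 5, VN: 5, FPN: 5, DMN: 5}
  t_points: 230
  within_network_r: 0.5
  between_network_r: 0.1
  homotopic_r0: 0.5
  homotopic_age_slope: {FPN: -0.004}
  cross_hemisphere_r: 0.03
screening:
  fd_max: 0.2
  snr_k: 2.0
threshold:
  method: absolute
  value: 0.2
community:
  gamma: 1.0
  n_runs_subject: 150
  n_runs_consensus: 100
  tau: 0.5
stats:
  alpha: 0.05
flow:
  by_group: true
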