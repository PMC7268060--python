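# Emulates the study-scale cohort: 22 subjects, 17 sessions, alpha band.
# Runs at the ERD level (session-mean ERD targets feed the models directly);
# raw-signal materialization at 165 trials/session x 500 Hz x 26 channels is
# far beyond a desktop budget and adds nothing to the statistics.
mode: synthetic-erd
out_dir: results/paper_like
seed: 20
bands: [alpha]
erd_method: per_trial
stage1_reml: true
stage1_correlated: true
cohort:
  n_subjects: 22
  sessions_per_subject: 17
  trials_per_session: 165
  fs: 500.0
  iti_range_s: [4.0, 7.0]
  prep_s: 2.0
  move_s: 5.0
  beta0: -30.0
  beta1: -0.5
  sd_b0: 10.0
  sd_b1: 0.4
  rho_b: 0.0
  sigma_eps: 8.0
  gamma: [2.0, 0.05, -4.0, -0.15]
  sigma_out: 3.0
rejection:
  hf_band: [110.0, 140.0]
  hf_z_threshold: 4.0
  offset_z_threshold: 20.0
  emg_wl_sd_threshold: 3.0
  min_trials_per_session: 16
  min_fraction: 0.10
  max_removed_sessions_fraction: 0.5
  eog_component_corr_threshold: 0.7
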