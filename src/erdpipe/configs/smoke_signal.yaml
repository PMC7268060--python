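# Small end-to-end signal-level run: raw multichannel sessions are
# materialized, pass the full artifact cascade, and ERD is measured
# spectrally before modeling.  Sized to finish in a couple of minutes.
mode: synthetic-signal
out_dir: results/smoke_signal
seed: 7
bands: [alpha]
erd_method: per_trial
cohort:
  n_subjects: 8
  sessions_per_subject: 4
  trials_per_session: 10
  sigma_eps: 4.0
  sd_b1: 1.5
  artifact_rates:
    hf_burst: 0.08
    offset: 0.05
    emg_paretic_rest: 0.08
    emg_healthy_move: 0.08
# session-size threshold scaled to the tiny smoke sessions (the protocol
# value of 16 assumes ~165 trials/session)
rejection:
  min_trials_per_session: 5
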