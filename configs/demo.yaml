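# Small demonstration cohort: 2 patients, 30 days, dense seizures with a
# strong cluster/isolated REN effect, short analysis windows for speed.
seed: 3
sim:
  n_patients: 2
  recording_days: 30
  isolated_rate: 0.45
  cluster_rate: 0.35
  cluster_size_p: 0.5
  max_cluster_size: 4
  inter_event_gap_extra_mean_h: 6.0
  seizure_duration_mean_s: 10.0
  seizure_duration_sd_s: 5.0
  duration_range_s: [3.0, 30.0]
  active_window_s: 30.0
  effect_near: 2.0
  effect_ictal: 1.0
preprocess:
  near_window_s: 30.0
taxonomy:
  isi_threshold_h: 24.0
cv:
  models: [logistic_regression, random_forest]
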