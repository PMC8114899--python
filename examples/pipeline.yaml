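# Full cohort pipeline config for `qeeg run-all`.
# Sections: preprocess, artifact, spectral, detector, epochs,
# synth_wt, synth_as, stats; unspecified keys keep the study defaults
# (bandpass 0.5-70 Hz, notch 60 Hz, FFT 2042/Hann/50%, spike 200 ms at
# 2x baseline, 2-min epochs every 10 min, 5000 bootstrap resamples).
n_per_group: 4
synth_wt:
  fs: 500
  duration_s: 120
  spike_rate_per_min: 0.2
synth_as:
  fs: 500
  duration_s: 120
  delta_mult: 1.7
  spike_rate_per_min: 2.0
epochs:
  window_start_s: 0
  window_end_s: 120
  epoch_len_s: 60
  stride_s: 60
stats:
  n_boot: 2000
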