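# Synthetic recording settings for `qeeg simulate`.
# All SynthConfig keys are accepted under `synth:`; unspecified keys
# keep their defaults (fs 2000 Hz, 300 s, WT-like band targets,
# no events, no artifacts).
synth:
  fs: 1000
  duration_s: 600
  spike_rate_per_min: 2
  delta_mult: 1.7
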