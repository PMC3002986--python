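# Reference adaptive-PIF configuration: stationary rate 0.1/ms,
# degree of adaptation alpha = 0.5, 100 stochastic adaptation channels.
base_drive: 0.2
adaptation_strength: 1.0
white_noise_intensity: 0.0
kinetics:
  n_channels: 100
  tau_a: 100.0
  pulse_duration: 1.0
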