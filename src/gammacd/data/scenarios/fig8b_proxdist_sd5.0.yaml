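# Subthreshold combined drive: 50 Hz proximal (sigma_p 2.5 ms) plus 50 Hz
# distal (sigma_d 5.0 ms) lagging the proximal cycle means by 5 ms.
name: fig8b_proxdist_sd5.0
layers: [L5]
network:
  regimes: [l5_weak_ping]
drives:
  - {type: burst, input_class: proximal, f_hz: 50.0, sigma_ms: 2.5, layer: L5}
  - {type: burst, input_class: distal, f_hz: 50.0, sigma_ms: 5.0, distal_lag_ms: 5.0, layer: L5}
seed: 0
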