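# Subthreshold 50 Hz proximal-only drive, sigma_p = 7.5 ms; no cortical
# spiking, CD oscillates at the drive frequency.
name: fig6c_prox50_sp7.5
layers: [L5]
network:
  regimes: [l5_weak_ping]
drives:
  - {type: burst, input_class: proximal, f_hz: 50.0, sigma_ms: 7.5, layer: L5}
seed: 0
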