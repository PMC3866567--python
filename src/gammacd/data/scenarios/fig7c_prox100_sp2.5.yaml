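# Subthreshold proximal-only drive at 100 Hz, sigma_p = 2.5 ms; spectral
# power decreases as the drive frequency increases (fig7a = fig6a, 50 Hz).
name: fig7c_prox100_sp2.5
layers: [L5]
network:
  regimes: [l5_weak_ping]
drives:
  - {type: burst, input_class: proximal, f_hz: 100.0, sigma_ms: 2.5, layer: L5}
seed: 0
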