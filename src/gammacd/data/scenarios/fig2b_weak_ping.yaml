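# Weak PING in L5 with the regime-table Poisson conductance (1e-2 uS).
name: fig2b_weak_ping
layers: [L5]
network:
  regimes: [l5_weak_ping]
drives:
  - {type: poisson, rate_hz: 40.0, g_max_uS: 1.0e-2, layer: L5, target: proximal}
seed: 0
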