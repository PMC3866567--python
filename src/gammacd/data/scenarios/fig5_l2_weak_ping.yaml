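# Weak PING in L2/3 with matched firing rates to the L5 regime; max |CD| is
# ~3x smaller than L5 (shorter apical length).
name: fig5_l2_weak_ping
layers: [L2/3]
network:
  regimes: [l2_weak_ping]
drives:
  - {type: poisson, rate_hz: 140.0, g_max_uS: 0.8e-3, layer: L2/3, target: proximal}
seed: 0
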