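# High-gamma epoch analysis: identical regime to fig3_weak_ping; epochs of
# 100-150 Hz power are single excitation-inhibition cycles, not a separate
# oscillator.
name: fig4_weak_ping_high_gamma
layers: [L5]
network:
  regimes: [l5_weak_ping_fig]
drives:
  - {type: poisson, rate_hz: 40.0, g_max_uS: 0.75e-2, layer: L5, target: proximal}
seed: 0
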