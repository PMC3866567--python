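# Weak PING in L5, reduced-conductance variant (0.75e-2 uS) used for the
# slope-ratio and high-gamma analyses; also the L5 reference for the
# laminar amplitude comparison.
name: fig3_weak_ping
layers: [L5]
network:
  regimes: [l5_weak_ping_fig]
drives:
  - {type: poisson, rate_hz: 40.0, g_max_uS: 0.75e-2, layer: L5, target: proximal}
seed: 0
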