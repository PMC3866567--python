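# Strong PING in L5: tonic drive, no I-I synapses; ~36 Hz, 18 cycles/500 ms.
name: fig2a_strong_ping
layers: [L5]
network:
  regimes: [l5_strong_ping]
drives:
  - {type: tonic, i_app: 6.0, layer: L5}
seed: 0
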