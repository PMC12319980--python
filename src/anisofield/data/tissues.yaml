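# Default ohmic tissue conductivities (S/m) and the uniform prior ranges used
# for uncertainty quantification. Values are literature-based low-frequency
# conductivities for fresh/live tissue near body temperature.
conductivities:
  wm: 0.126
  gm: 0.275
  csf: 1.654
  spongy_bone: 0.025
  compact_bone: 0.008
  scalp: 0.465
  eyes: 0.5
  blood: 0.6
  muscle: 0.16
  electrode_rubber: 29.0
  conductive_gel: 1.0
ranges:
  wm: [0.1, 0.4]
  gm: [0.1, 0.6]
  csf: [0.8, 1.8]
  spongy_bone: [0.015, 0.040]
  compact_bone: [0.003, 0.012]
  scalp: [0.2, 1.0]
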