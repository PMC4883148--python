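# Two-weight search: recover a drive strong enough for execution and feeling.
kind: calibration
free_parameters:
  "SR(s)->PA": [0.0, 1.0]
  "PA->EA": [0.0, 1.0]
scenarios:
  1:
    - {kind: lower_bound, subjects: ["EA(a1)"], parameters: {value: 0.4}}
    - {kind: lower_bound, subjects: ["F(b1)"], parameters: {value: 0.3}}
budget: 120
seed: 7
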