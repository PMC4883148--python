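# Start from the veto scenario but weaken the prediction less severely.
kind: scenario
id: 3
overrides:
  "PA->SR(b)": 0.4
horizon: 120
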