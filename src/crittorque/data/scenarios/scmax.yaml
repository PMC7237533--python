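name: SCmax
x0:
- 1.0
- 1.0
stages:
- duration_s: 3600.0
  mode: relative
  level: 1.0
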