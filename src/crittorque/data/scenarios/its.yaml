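name: ITS
x0:
- 1.0
- 1.0
stages:
- duration_s: 180.0
  mode: relative
  level: 1.0
- duration_s: 10.0
  mode: relative
  level: 0.0
- duration_s: 2.0
  mode: relative
  level: 1.0
- duration_s: 18.0
  mode: relative
  level: 0.0
- duration_s: 2.0
  mode: relative
  level: 1.0
- duration_s: 28.0
  mode: relative
  level: 0.0
- duration_s: 2.0
  mode: relative
  level: 1.0
- duration_s: 58.0
  mode: relative
  level: 0.0
- duration_s: 2.0
  mode: relative
  level: 1.0
- duration_s: 178.0
  mode: relative
  level: 0.0
- duration_s: 2.0
  mode: relative
  level: 1.0
- duration_s: 298.0
  mode: relative
  level: 0.0
- duration_s: 2.0
  mode: relative
  level: 1.0
- duration_s: 298.0
  mode: relative
  level: 0.0
- duration_s: 2.0
  mode: relative
  level: 1.0
- duration_s: 298.0
  mode: relative
  level: 0.0
- duration_s: 2.0
  mode: relative
  level: 1.0
- duration_s: 298.0
  mode: relative
  level: 0.0
- duration_s: 2.0
  mode: relative
  level: 1.0
- duration_s: 298.0
  mode: relative
  level: 0.0
- duration_s: 2.0
  mode: relative
  level: 1.0
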