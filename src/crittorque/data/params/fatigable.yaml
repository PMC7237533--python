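p:
- 0.0024
- 0.00756
- 0.0027
- 1.2
- 0.00375
name: fatigable
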