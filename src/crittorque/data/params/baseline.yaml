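p:
- 0.0026
- 0.007
- 0.0028
- 1.5
- 0.003
name: baseline
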