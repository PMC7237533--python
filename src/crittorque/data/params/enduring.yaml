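p:
- 0.0028
- 0.0062
- 0.003
- 2.0
- 0.0021
name: enduring
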