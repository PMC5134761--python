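torsions:
- name: T1
  lower: -90.0
  upper: 90.0
  periodic: false
  half_spacing: 30.0
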