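torsions:
- name: T1
  lower: 0.0
  upper: 360.0
  periodic: true
  half_spacing: 15.0
- name: T2
  lower: 165.0
  upper: 195.0
  periodic: false
  half_spacing: 15.0
- name: T3
  lower: 95.0
  upper: 185.0
  periodic: false
  half_spacing: 15.0
- name: T4
  lower: 55.0
  upper: 115.0
  periodic: false
  half_spacing: 15.0
- name: T5
  lower: 95.0
  upper: 185.0
  periodic: false
  half_spacing: 15.0
- name: T6
  lower: 165.0
  upper: 195.0
  periodic: false
  half_spacing: 15.0
- name: T7
  lower: 0.0
  upper: 360.0
  periodic: true
  half_spacing: 15.0
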