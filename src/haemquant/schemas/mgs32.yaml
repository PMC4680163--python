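# Modified Graeb scale over eight ventricular compartments, each scored by
# quartile of blood filling (1: <=25 % .. 4: >75 %).  Maximum 32.
# Set expansion_bonus: 1 to award an extra point per expanded ventricle; this
# raises the attainable maximum above 32 and is disabled by default.
name: mgs32
max_score: 32
expansion_bonus: 0
compartments:
  - name: left_frontal_body
    ventricle: left_lateral
    rule: quartile
  - name: right_frontal_body
    ventricle: right_lateral
    rule: quartile
  - name: left_temporal
    ventricle: left_lateral
    rule: quartile
  - name: right_temporal
    ventricle: right_lateral
    rule: quartile
  - name: left_occipital
    ventricle: left_lateral
    rule: quartile
  - name: right_occipital
    ventricle: right_lateral
    rule: quartile
  - name: third
    ventricle: third
    rule: quartile
  - name: fourth
    ventricle: fourth
    rule: quartile
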