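# Classic Graeb scale: lateral ventricles 1 (trace) .. 4 (full and expanded),
# third and fourth ventricles 1 (blood present) or 2 (filled and expanded).
# Maximum 12.
name: classic_graeb
max_score: 12
expansion_bonus: 0
compartments:
  - name: left_lateral
    ventricle: left_lateral
    rule: lateral_classic
    aggregates: [left_frontal_body, left_temporal, left_occipital]
  - name: right_lateral
    ventricle: right_lateral
    rule: lateral_classic
    aggregates: [right_frontal_body, right_temporal, right_occipital]
  - name: third
    ventricle: third
    rule: small_classic
  - name: fourth
    ventricle: fourth
    rule: small_classic
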