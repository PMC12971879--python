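# Modified Mediterranean diet score configuration.
#
# Beneficial components score 1 when the subject lies strictly above the cohort
# median (values equal to the median score 0); reverse-coded components score 1
# strictly below the median; alcohol scores 1 inside the recommended range
# (inclusive, g/day). fat_ratio = (MUFA + PUFA) / SFA is computed from the
# intake table. Maximum attainable total = 10.
beneficial:
  - vegetables
  - legumes
  - fruit_nuts
  - fish_seafood
  - cereals
  - fat_ratio
reverse_coded:
  - meat
  - meat_products
  - dairy
alcohol_range: [5.0, 25.0]
fat_ratio:
  numerator: [mufa, pufa]
  denominator: saturated_fat
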