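# Component scoring standards for the modified AHEI (6 components, each
# scored 0-10 by linear interpolation between zero_score_servings and
# full_score_servings, clamped).  Reverse-scored components (foods to
# limit) put the 10-point anchor at zero intake.  Cutoffs follow the
# AHEI-2010 servings criteria where the instrument's frequency-only
# capture permits (vegetables 5/d, fruit 4/d, nuts/legumes 1/d, SSB+juice
# reverse at 1/d, red/processed meat reverse at 1.5/d); the grams-based
# whole-grain criterion is replaced by a 1.5 servings/d anchor.
vegetables:
  direction: positive
  zero_score_servings: 0.0
  full_score_servings: 5.0
fruit:
  direction: positive
  zero_score_servings: 0.0
  full_score_servings: 4.0
whole_grains:
  direction: positive
  zero_score_servings: 0.0
  full_score_servings: 1.5
nuts_legumes:
  direction: positive
  zero_score_servings: 0.0
  full_score_servings: 1.0
ssb_juice:
  direction: reverse
  zero_score_servings: 1.0
  full_score_servings: 0.0
red_processed_meat:
  direction: reverse
  zero_score_servings: 1.5
  full_score_servings: 0.0
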