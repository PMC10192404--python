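{
  "comment": "Child healthy-eating psychosocial scales (4-point Likert, no neutral midpoint). Item ids follow the item wordings quoted in the study tables; the full instrument wording is unpublished, so these definitions are a documented synthetic stand-in. Scales overlap: subscales reference subsets of the same items.",
  "items": {
    "tc_fruit_snack": "I usually choose to eat fruit during snack time",
    "tc_fruit_meal": "I usually choose to eat fruit with my meal",
    "tc_fruit_dessert": "I usually choose fruit for dessert",
    "tc_veg_lunch": "I usually choose to eat vegetable at lunch",
    "tc_veg_dinner": "I usually choose to eat vegetable at dinner",
    "tc_veg_snack": "I usually choose vegetables for a snack",
    "se_fruit_lunch": "I can eat fruit at lunch",
    "se_fruit_dessert": "I can eat fruit for dessert",
    "se_fruit_cereal": "I can add fruit to my cereal for breakfast",
    "se_fruit_bring": "I can bring fruit to school for lunch",
    "se_veg_lunch": "I can eat vegetables served at lunch",
    "se_veg_dinner": "I can eat a serving of vegetables for dinner",
    "se_veg_bring": "I can bring a lunch to school with a vegetable",
    "se_veg_cook": "I can help cook vegetables at home"
  },
  "scales": [
    {"scale_id": "tendency_fruits", "item_ids": ["tc_fruit_snack", "tc_fruit_meal", "tc_fruit_dessert"],
     "subscales": {"tc_fruit_snack": "fruit", "tc_fruit_meal": "fruit", "tc_fruit_dessert": "fruit"}},
    {"scale_id": "tendency_vegetables", "item_ids": ["tc_veg_lunch", "tc_veg_dinner", "tc_veg_snack"],
     "subscales": {"tc_veg_lunch": "vegetable", "tc_veg_dinner": "vegetable", "tc_veg_snack": "vegetable"}},
    {"scale_id": "tendency_fv", "item_ids": ["tc_fruit_snack", "tc_fruit_meal", "tc_fruit_dessert", "tc_veg_lunch", "tc_veg_dinner", "tc_veg_snack"],
     "subscales": {"tc_fruit_snack": "fruit", "tc_fruit_meal": "fruit", "tc_fruit_dessert": "fruit", "tc_veg_lunch": "vegetable", "tc_veg_dinner": "vegetable", "tc_veg_snack": "vegetable"}},
    {"scale_id": "se_fruits_eat", "item_ids": ["se_fruit_lunch", "se_fruit_dessert", "se_fruit_cereal"],
     "subscales": {"se_fruit_lunch": "fruit", "se_fruit_dessert": "fruit", "se_fruit_cereal": "fruit"}},
    {"scale_id": "se_fruits_4", "item_ids": ["se_fruit_lunch", "se_fruit_dessert", "se_fruit_cereal", "se_fruit_bring"],
     "subscales": {"se_fruit_lunch": "fruit", "se_fruit_dessert": "fruit", "se_fruit_cereal": "fruit", "se_fruit_bring": "fruit"}},
    {"scale_id": "se_veg_eat", "item_ids": ["se_veg_lunch", "se_veg_dinner"],
     "subscales": {"se_veg_lunch": "vegetable", "se_veg_dinner": "vegetable"}},
    {"scale_id": "se_veg_4", "item_ids": ["se_veg_lunch", "se_veg_dinner", "se_veg_bring", "se_veg_cook"],
     "subscales": {"se_veg_lunch": "vegetable", "se_veg_dinner": "vegetable", "se_veg_bring": "vegetable", "se_veg_cook": "vegetable"}},
    {"scale_id": "se_fv_5", "item_ids": ["se_fruit_lunch", "se_fruit_dessert", "se_fruit_cereal", "se_veg_lunch", "se_veg_dinner"],
     "subscales": {"se_fruit_lunch": "fruit", "se_fruit_dessert": "fruit", "se_fruit_cereal": "fruit", "se_veg_lunch": "vegetable", "se_veg_dinner": "vegetable"}},
    {"scale_id": "se_fv_8", "item_ids": ["se_fruit_lunch", "se_fruit_dessert", "se_fruit_cereal", "se_fruit_bring", "se_veg_lunch", "se_veg_dinner", "se_veg_bring", "se_veg_cook"],
     "subscales": {"se_fruit_lunch": "fruit", "se_fruit_dessert": "fruit", "se_fruit_cereal": "fruit", "se_fruit_bring": "fruit", "se_veg_lunch": "vegetable", "se_veg_dinner": "vegetable", "se_veg_bring": "vegetable", "se_veg_cook": "vegetable"}}
  ]
}
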