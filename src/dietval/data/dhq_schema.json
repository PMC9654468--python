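{
 "items": [
  {
   "item_id": "d01_breakfast_cereal",
   "prompt_class": "frequency",
   "reversed": false,
   "sub_score": "cereal",
   "scored": true,
   "categories": [
    "lt1_per_week",
    "1_2_per_week",
    "3_4_per_week",
    "5_6_per_week",
    "6plus_per_week"
   ],
   "points": [
    1,
    2,
    3,
    4,
    5
   ]
  },
  {
   "item_id": "d02_wholemeal_bread",
   "prompt_class": "frequency",
   "reversed": false,
   "sub_score": "cereal",
   "scored": true,
   "categories": [
    "lt1_per_week",
    "1_2_per_week",
    "3_4_per_week",
    "5_6_per_week",
    "6plus_per_week"
   ],
   "points": [
    1,
    2,
    3,
    4,
    5
   ]
  },
  {
   "item_id": "d03_other_cereals",
   "prompt_class": "frequency",
   "reversed": false,
   "sub_score": "cereal",
   "scored": true,
   "categories": [
    "lt1_per_week",
    "1_2_per_week",
    "3_4_per_week",
    "5_6_per_week",
    "6plus_per_week"
   ],
   "points": [
    1,
    2,
    3,
    4,
    5
   ]
  },
  {
   "item_id": "d04_fruit_serves",
   "prompt_class": "fv_quantity",
   "reversed": false,
   "sub_score": "fruit_veg",
   "scored": true,
   "categories": [
    "lt1_piece",
    "one_piece",
    "two_plus_pieces"
   ],
   "points": [
    1,
    3,
    5
   ]
  },
  {
   "item_id": "d05_vegetable_serves",
   "prompt_class": "fv_quantity",
   "reversed": false,
   "sub_score": "fruit_veg",
   "scored": true,
   "categories": [
    "lt1_piece",
    "one_piece",
    "two_plus_pieces"
   ],
   "points": [
    1,
    3,
    5
   ]
  },
  {
   "item_id": "d06_vegetable_types",
   "prompt_class": "veg_types",
   "reversed": false,
   "sub_score": "fruit_veg",
   "scored": true,
   "categories": [
    "none",
    "one",
    "two",
    "three",
    "four",
    "five_plus"
   ],
   "points": [
    1,
    1,
    2,
    3,
    4,
    5
   ]
  },
  {
   "item_id": "d07_takeaway_foods",
   "prompt_class": "frequency",
   "reversed": true,
   "sub_score": "takeaway",
   "scored": true,
   "categories": [
    "lt1_per_week",
    "1_2_per_week",
    "3_4_per_week",
    "5_6_per_week",
    "6plus_per_week"
   ],
   "points": [
    1,
    2,
    3,
    4,
    5
   ]
  },
  {
   "item_id": "d08_pastries_cakes",
   "prompt_class": "frequency",
   "reversed": true,
   "sub_score": "takeaway",
   "scored": true,
   "categories": [
    "lt1_per_week",
    "1_2_per_week",
    "3_4_per_week",
    "5_6_per_week",
    "6plus_per_week"
   ],
   "points": [
    1,
    2,
    3,
    4,
    5
   ]
  },
  {
   "item_id": "d09_processed_meat",
   "prompt_class": "frequency",
   "reversed": true,
   "sub_score": "takeaway",
   "scored": true,
   "categories": [
    "lt1_per_week",
    "1_2_per_week",
    "3_4_per_week",
    "5_6_per_week",
    "6plus_per_week"
   ],
   "points": [
    1,
    2,
    3,
    4,
    5
   ]
  },
  {
   "item_id": "d10_legumes",
   "prompt_class": "frequency",
   "reversed": false,
   "sub_score": "fiber",
   "scored": true,
   "categories": [
    "lt1_per_week",
    "1_2_per_week",
    "3_4_per_week",
    "5_6_per_week",
    "6plus_per_week"
   ],
   "points": [
    1,
    2,
    3,
    4,
    5
   ]
  },
  {
   "item_id": "d11_nuts_seeds",
   "prompt_class": "frequency",
   "reversed": false,
   "sub_score": "fiber",
   "scored": true,
   "categories": [
    "lt1_per_week",
    "1_2_per_week",
    "3_4_per_week",
    "5_6_per_week",
    "6plus_per_week"
   ],
   "points": [
    1,
    2,
    3,
    4,
    5
   ]
  },
  {
   "item_id": "d12_reduced_fat_dairy",
   "prompt_class": "frequency",
   "reversed": false,
   "sub_score": "fat",
   "scored": true,
   "categories": [
    "lt1_per_week",
    "1_2_per_week",
    "3_4_per_week",
    "5_6_per_week",
    "6plus_per_week"
   ],
   "points": [
    1,
    2,
    3,
    4,
    5
   ]
  },
  {
   "item_id": "d13_cooking_fat",
   "prompt_class": "fat_choice",
   "reversed": false,
   "sub_score": "fat",
   "scored": true,
   "categories": [
    "solid_fat",
    "mostly_solid",
    "blend",
    "mostly_unsaturated",
    "unsaturated"
   ],
   "points": [
    1,
    2,
    3,
    4,
    5
   ]
  },
  {
   "item_id": "d14_fish",
   "prompt_class": "frequency",
   "reversed": false,
   "sub_score": "omega3",
   "scored": true,
   "categories": [
    "lt1_per_week",
    "1_2_per_week",
    "3_4_per_week",
    "5_6_per_week",
    "6plus_per_week"
   ],
   "points": [
    1,
    2,
    3,
    4,
    5
   ]
  },
  {
   "item_id": "d15_oily_fish",
   "prompt_class": "frequency",
   "reversed": false,
   "sub_score": "omega3",
   "scored": true,
   "categories": [
    "lt1_per_week",
    "1_2_per_week",
    "3_4_per_week",
    "5_6_per_week",
    "6plus_per_week"
   ],
   "points": [
    1,
    2,
    3,
    4,
    5
   ]
  },
  {
   "item_id": "d16_spreads",
   "prompt_class": "fat_choice",
   "reversed": false,
   "sub_score": "food_choices",
   "scored": true,
   "categories": [
    "solid_fat",
    "mostly_solid",
    "blend",
    "mostly_unsaturated",
    "unsaturated"
   ],
   "points": [
    1,
    2,
    3,
    4,
    5
   ]
  },
  {
   "item_id": "d17_salad_dressing",
   "prompt_class": "fat_choice",
   "reversed": false,
   "sub_score": "food_choices",
   "scored": true,
   "categories": [
    "solid_fat",
    "mostly_solid",
    "blend",
    "mostly_unsaturated",
    "unsaturated"
   ],
   "points": [
    1,
    2,
    3,
    4,
    5
   ]
  },
  {
   "item_id": "d18_cooking_sauces",
   "prompt_class": "fat_choice",
   "reversed": false,
   "sub_score": "food_choices",
   "scored": true,
   "categories": [
    "solid_fat",
    "mostly_solid",
    "blend",
    "mostly_unsaturated",
    "unsaturated"
   ],
   "points": [
    1,
    2,
    3,
    4,
    5
   ]
  },
  {
   "item_id": "d19_preparation_method",
   "prompt_class": "preparation",
   "reversed": false,
   "sub_score": "food_preparation",
   "scored": true,
   "categories": [
    "deep_frying",
    "shallow_frying",
    "roasting_in_fat",
    "grilling_stirfry",
    "steam_poach_microwave"
   ],
   "points": [
    1,
    2,
    3,
    4,
    5
   ]
  },
  {
   "item_id": "d20_fried_food",
   "prompt_class": "frequency",
   "reversed": true,
   "sub_score": "food_preparation",
   "scored": true,
   "categories": [
    "lt1_per_week",
    "1_2_per_week",
    "3_4_per_week",
    "5_6_per_week",
    "6plus_per_week"
   ],
   "points": [
    1,
    2,
    3,
    4,
    5
   ]
  },
  {
   "item_id": "d21_water_intake",
   "prompt_class": "frequency",
   "reversed": false,
   "sub_score": null,
   "scored": false,
   "categories": [
    "lt1_per_week",
    "1_2_per_week",
    "3_4_per_week",
    "5_6_per_week",
    "6plus_per_week"
   ],
   "points": [
    1,
    2,
    3,
    4,
    5
   ]
  },
  {
   "item_id": "d22_meals_away_from_home",
   "prompt_class": "frequency",
   "reversed": false,
   "sub_score": null,
   "scored": false,
   "categories": [
    "lt1_per_week",
    "1_2_per_week",
    "3_4_per_week",
    "5_6_per_week",
    "6plus_per_week"
   ],
   "points": [
    1,
    2,
    3,
    4,
    5
   ]
  },
  {
   "item_id": "d23_snacking",
   "prompt_class": "frequency",
   "reversed": false,
   "sub_score": null,
   "scored": false,
   "categories": [
    "lt1_per_week",
    "1_2_per_week",
    "3_4_per_week",
    "5_6_per_week",
    "6plus_per_week"
   ],
   "points": [
    1,
    2,
    3,
    4,
    5
   ]
  },
  {
   "item_id": "d24_supplement_use",
   "prompt_class": "frequency",
   "reversed": false,
   "sub_score": null,
   "scored": false,
   "categories": [
    "lt1_per_week",
    "1_2_per_week",
    "3_4_per_week",
    "5_6_per_week",
    "6plus_per_week"
   ],
   "points": [
    1,
    2,
    3,
    4,
    5
   ]
  }
 ]
}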