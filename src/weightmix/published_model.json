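{
 "leaves": [
  {
   "bias": 2.12,
   "id": 1,
   "selected_zero": [
    "base_drinking"
   ],
   "terms": {
    "age": -0.02,
    "base_daily_activity_no": -0.34,
    "base_eating_normal": -0.08,
    "base_exercise_no": -0.36,
    "base_fast_walker_no": -0.02,
    "base_heavy_smoker_no": -0.29,
    "base_late_supper_yes": -0.28,
    "base_skips_breakfast_yes": -0.18,
    "base_sleeps_well_no": -0.22,
    "base_snacks_yes": -0.15,
    "height": 0.01,
    "pred_daily_activity_yes_i1": -0.36,
    "pred_daily_activity_yes_i2": -0.01,
    "pred_drinking": 0.01,
    "pred_eating_normal_i1": -0.34,
    "pred_eating_normal_i2": 0.06,
    "pred_eating_normal_i3": -0.67,
    "pred_eating_slower_i1": -1.07,
    "pred_eating_slower_i3": -1.84,
    "pred_exercise_no_i1": 0.09,
    "pred_exercise_yes_i1": -0.61,
    "pred_exercise_yes_i2": -0.74,
    "pred_exercise_yes_i3": -0.42,
    "pred_fast_walker_yes_i1": -0.13,
    "pred_fast_walker_yes_i3": -0.07,
    "pred_heavy_smoker_no_i1": -0.11,
    "pred_late_supper_no_i1": -0.02,
    "pred_late_supper_no_i2": -0.61,
    "pred_late_supper_no_i3": -0.61,
    "pred_skips_breakfast_no_i1": -0.24,
    "pred_skips_breakfast_no_i2": -0.24,
    "pred_skips_breakfast_no_i3": -0.67,
    "pred_sleeps_well_yes_i1": -0.11,
    "pred_sleeps_well_yes_i2": -0.37,
    "pred_snacks_no_i1": -0.35,
    "pred_snacks_no_i2": -0.47,
    "pred_snacks_no_i3": -0.26,
    "pred_wants_instruction_yes": -0.11,
    "weight_baseline": 1.0,
    "weight_diff": -0.14
   }
  },
  {
   "bias": -2.34,
   "id": 2,
   "selected_zero": [],
   "terms": {
    "base_daily_activity_no": -0.2,
    "base_drinking": -0.01,
    "base_eating_normal": 0.07,
    "base_eating_quicker": -0.39,
    "base_fast_walker_no": -0.26,
    "base_heavy_smoker_no": -0.45,
    "base_late_supper_yes": -0.63,
    "base_sleeps_well_no": -0.31,
    "base_snacks_yes": -0.02,
    "height": 0.03,
    "pred_daily_activity_yes_i1": -0.35,
    "pred_daily_activity_yes_i2": -0.07,
    "pred_drinking": 0.03,
    "pred_eating_normal_i1": -0.35,
    "pred_eating_normal_i2": 0.27,
    "pred_eating_normal_i3": 0.31,
    "pred_eating_slower_i2": -0.22,
    "pred_eating_slower_i3": -1.12,
    "pred_fast_walker_yes_i1": -0.01,
    "pred_fast_walker_yes_i2": -0.03,
    "pred_fast_walker_yes_i3": -0.59,
    "pred_heavy_smoker_no_i1": -0.3,
    "pred_heavy_smoker_no_i3": -1.15,
    "pred_late_supper_no_i1": -0.39,
    "pred_late_supper_no_i3": -0.03,
    "pred_skips_breakfast_no_i2": -0.5,
    "pred_sleeps_well_yes_i1": -0.29,
    "pred_snacks_no_i1": -0.12,
    "pred_snacks_no_i2": -1.72,
    "pred_snacks_no_i3": -1.45,
    "pred_wants_instruction_yes": -0.06,
    "weight_baseline": 1.0,
    "weight_diff": -0.13
   }
  },
  {
   "bias": 1.57,
   "id": 3,
   "selected_zero": [
    "height",
    "pred_drinking",
    "pred_eating_slower_i2"
   ],
   "terms": {
    "age": -0.02,
    "base_daily_activity_no": -0.14,
    "base_drinking": -0.01,
    "base_eating_normal": 0.04,
    "base_exercise_no": -0.25,
    "base_fast_walker_no": -0.09,
    "base_late_supper_yes": -0.1,
    "base_snacks_yes": -0.21,
    "pred_daily_activity_yes_i1": -0.13,
    "pred_daily_activity_yes_i2": -0.03,
    "pred_daily_activity_yes_i3": -0.1,
    "pred_eating_normal_i1": -0.04,
    "pred_eating_normal_i2": -0.19,
    "pred_eating_normal_i3": -0.06,
    "pred_eating_slower_i1": -0.01,
    "pred_exercise_no_i1": 0.24,
    "pred_exercise_yes_i2": -0.05,
    "pred_fast_walker_yes_i1": -0.03,
    "pred_fast_walker_yes_i2": -0.03,
    "pred_heavy_smoker_no_i2": -0.11,
    "pred_heavy_smoker_no_i3": -0.16,
    "pred_late_supper_no_i1": -0.16,
    "pred_late_supper_no_i3": -0.16,
    "pred_skips_breakfast_no_i2": -0.06,
    "pred_skips_breakfast_no_i3": -0.13,
    "pred_sleeps_well_yes_i2": -0.07,
    "pred_sleeps_well_yes_i3": -0.12,
    "pred_snacks_no_i1": -0.16,
    "pred_snacks_no_i2": -0.13,
    "pred_snacks_no_i3": -0.18,
    "weight_baseline": 1.0,
    "weight_diff": -0.19
   }
  },
  {
   "bias": 0.16,
   "id": 4,
   "selected_zero": [
    "base_drinking",
    "pred_drinking",
    "pred_fast_walker_yes_i2",
    "pred_eating_slower_i3",
    "base_snacks_yes",
    "pred_snacks_no_i2"
   ],
   "terms": {
    "age": -0.01,
    "base_daily_activity_no": -0.06,
    "base_eating_normal": 0.03,
    "base_eating_quicker": -0.01,
    "base_exercise_no": -0.11,
    "base_fast_walker_no": -0.02,
    "height": 0.01,
    "pred_daily_activity_yes_i1": -0.11,
    "pred_daily_activity_yes_i2": -0.03,
    "pred_daily_activity_yes_i3": -0.06,
    "pred_eating_normal_i1": -0.07,
    "pred_eating_normal_i2": -0.15,
    "pred_eating_normal_i3": -0.03,
    "pred_eating_slower_i1": -0.14,
    "pred_eating_slower_i2": -0.03,
    "pred_exercise_no_i1": 0.11,
    "pred_exercise_yes_i3": -0.01,
    "pred_fast_walker_yes_i1": -0.04,
    "pred_heavy_smoker_no_i3": -0.02,
    "pred_late_supper_no_i1": -0.07,
    "pred_late_supper_no_i2": -0.11,
    "pred_late_supper_no_i3": -0.19,
    "pred_skips_breakfast_no_i1": -0.09,
    "pred_skips_breakfast_no_i2": -0.01,
    "pred_skips_breakfast_no_i3": -0.01,
    "pred_sleeps_well_yes_i2": -0.07,
    "pred_sleeps_well_yes_i3": -0.02,
    "pred_snacks_no_i1": -0.05,
    "pred_snacks_no_i3": -0.11,
    "pred_wants_instruction_yes": -0.03,
    "weight_baseline": 1.0,
    "weight_diff": -0.21
   }
  },
  {
   "bias": 0.18,
   "id": 5,
   "selected_zero": [],
   "terms": {
    "base_daily_activity_no": -0.27,
    "base_drinking": -0.01,
    "base_eating_normal": -0.01,
    "base_eating_quicker": -0.41,
    "base_exercise_no": -0.04,
    "base_heavy_smoker_no": -0.92,
    "base_skips_breakfast_yes": -0.04,
    "base_sleeps_well_no": -0.09,
    "base_snacks_yes": -0.49,
    "height": 0.02,
    "pred_daily_activity_yes_i1": -0.25,
    "pred_daily_activity_yes_i3": -1.79,
    "pred_drinking": 0.01,
    "pred_eating_normal_i1": -0.52,
    "pred_eating_normal_i2": -1.48,
    "pred_eating_normal_i3": -0.33,
    "pred_eating_slower_i1": -0.75,
    "pred_eating_slower_i2": -1.65,
    "pred_exercise_yes_i1": -0.15,
    "pred_exercise_yes_i2": -0.58,
    "pred_fast_walker_yes_i1": -0.03,
    "pred_fast_walker_yes_i2": -0.37,
    "pred_fast_walker_yes_i3": -0.08,
    "pred_heavy_smoker_no_i1": -0.79,
    "pred_heavy_smoker_no_i2": -0.79,
    "pred_late_supper_no_i1": -0.21,
    "pred_late_supper_no_i2": -0.3,
    "pred_skips_breakfast_no_i1": -0.32,
    "pred_skips_breakfast_no_i3": -0.11,
    "pred_sleeps_well_yes_i2": -0.33,
    "pred_snacks_no_i1": -0.29,
    "pred_snacks_no_i2": -0.28,
    "pred_snacks_no_i3": -1.3,
    "weight_baseline": 1.0,
    "weight_diff": -0.22
   }
  }
 ],
 "meta": {
  "checksum": "f394f3c1ccc86706ad3db3488a1d3f0c41c94483a10c8ef1b258519b19b044ca",
  "leaf_order": "IDs 1-5 left-to-right: high-BMI male, high-BMI female, mid-BMI age<=24, mid-BMI age>24, low-BMI",
  "source": "published five-formula piecewise-linear body-weight model (gating schema and printed coefficient table)",
  "version": "1.0"
 },
 "tree": {
  "feature": "bmi",
  "if_false": {
   "feature": "bmi",
   "if_false": {
    "leaf": 5
   },
   "if_true": {
    "feature": "age",
    "if_false": {
     "leaf": 4
    },
    "if_true": {
     "leaf": 3
    },
    "op": "le",
    "threshold": 24.0
   },
   "op": "ge",
   "threshold": 23.44
  },
  "if_true": {
   "category": "male",
   "feature": "sex",
   "if_false": {
    "leaf": 2
   },
   "if_true": {
    "leaf": 1
   },
   "op": "eq"
  },
  "op": "ge",
  "threshold": 29.93
 }
}
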