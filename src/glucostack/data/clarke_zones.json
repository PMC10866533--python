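{
  "description": "Clarke error-grid zone predicates over (reference, predicted) glucose pairs in mg/dL. Zones are evaluated in the listed precedence; the final zone is the catch-all. Within a predicate object all conditions AND together; a zone's list of predicates ORs. Bounds are inclusive. 'rel_error_max' means |predicted - reference| <= value * reference. 'pred_min_line'/'pred_max_line' mean predicted >= / <= slope * reference + intercept.",
  "precedence": ["A", "E", "C", "D", "B"],
  "zones": {
    "A": [
      {"ref_max": 70, "pred_max": 70},
      {"rel_error_max": 0.2}
    ],
    "E": [
      {"ref_min": 180, "pred_max": 70},
      {"ref_max": 70, "pred_min": 180}
    ],
    "C": [
      {"ref_min": 70, "ref_max": 290, "pred_min_line": {"slope": 1.0, "intercept": 110.0}},
      {"ref_min": 130, "ref_max": 180, "pred_max_line": {"slope": 1.4, "intercept": -182.0}}
    ],
    "D": [
      {"ref_min": 240, "pred_min": 70, "pred_max": 180},
      {"ref_max": 58.333333333333336, "pred_min": 70, "pred_max": 180},
      {"ref_min": 58.333333333333336, "ref_max": 70, "pred_min_line": {"slope": 1.2, "intercept": 0.0}}
    ],
    "B": "otherwise"
  }
}
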