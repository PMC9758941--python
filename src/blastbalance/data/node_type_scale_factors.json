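{
  "description": "Published normalized runtimes of the five hot BLASTN functions on six node types, relative to the reference Type V nodes (all factors 1.0 on Type V). A factor above 1 means the function runs proportionally slower on that type.",
  "reference_node_type": "V",
  "factors": {
    "I":   {"func_a": 0.7301, "func_b": 0.7941, "func_c": 0.8018, "func_d": 0.6942, "func_e": 0.7163},
    "II":  {"func_a": 1.4077, "func_b": 1.3814, "func_c": 1.4704, "func_d": 1.4758, "func_e": 1.4249},
    "III": {"func_a": 1.5865, "func_b": 1.4713, "func_c": 1.5186, "func_d": 1.6585, "func_e": 1.5763},
    "IV":  {"func_a": 1.0775, "func_b": 1.0833, "func_c": 1.0689, "func_d": 1.0806, "func_e": 1.0743},
    "V":   {"func_a": 1.0, "func_b": 1.0, "func_c": 1.0, "func_d": 1.0, "func_e": 1.0},
    "VI":  {"func_a": 1.0018, "func_b": 1.0912, "func_c": 1.1191, "func_d": 0.9484, "func_e": 0.9910}
  }
}
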