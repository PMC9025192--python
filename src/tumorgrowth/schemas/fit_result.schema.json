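{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "tumorgrowth fit result record",
  "type": "object",
  "required": [
    "subject_id", "law", "status", "V0", "Vinf", "vinf_ratio",
    "rate_per_day", "composite_rate_per_day", "chi2_per_dof", "n_obs"
  ],
  "properties": {
    "subject_id": { "type": "string" },
    "law": { "type": "string", "enum": ["gompertz", "logistic"] },
    "status": { "type": "string", "enum": ["point_estimate", "bound"] },
    "V0": { "type": "number" },
    "Vinf": { "type": "number" },
    "vinf_ratio": { "type": "number" },
    "rate_per_day": { "type": "number" },
    "composite_rate_per_day": { "type": "number" },
    "chi2_per_dof": { "type": "number" },
    "sse_log": { "type": "number" },
    "n_obs": { "type": "integer" },
    "vinf_ratio_bound": {
      "type": "object",
      "required": ["direction", "value"],
      "properties": {
        "direction": { "type": "string", "enum": ["<", ">"] },
        "value": { "type": "number" }
      }
    },
    "rate_bound": {
      "type": "object",
      "required": ["direction", "value"],
      "properties": {
        "direction": { "type": "string", "enum": ["<", ">"] },
        "value": { "type": "number" }
      }
    }
  }
}
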