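{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "tumorgrowth forecast record",
  "type": "object",
  "required": ["subject_id", "cutoff_day", "exponential_regime", "fit", "points"],
  "properties": {
    "subject_id": { "type": "string" },
    "cutoff_day": { "type": "number" },
    "exponential_regime": { "type": "boolean" },
    "fit": { "type": "object" },
    "points": { "type": "array" }
  }
}
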