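{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "liquidecg evaluation report",
  "type": "object",
  "required": ["threshold", "n_records", "per_class", "macro"],
  "properties": {
    "threshold": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1},
    "n_records": {"type": "integer", "minimum": 1},
    "per_class": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["precision", "recall", "f1", "auroc"],
        "properties": {
          "precision": {"type": "number", "minimum": 0, "maximum": 1},
          "recall": {"type": "number", "minimum": 0, "maximum": 1},
          "f1": {"type": "number", "minimum": 0, "maximum": 1},
          "auroc": {"type": ["number", "null"], "minimum": 0, "maximum": 1},
          "precision_defined": {"type": "boolean"},
          "recall_defined": {"type": "boolean"}
        }
      }
    },
    "macro": {
      "type": "object",
      "required": ["precision", "recall", "f1", "auroc"],
      "additionalProperties": {"type": ["number", "null"]}
    }
  }
}
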