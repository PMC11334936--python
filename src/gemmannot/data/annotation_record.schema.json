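{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "gemmannot annotation records",
  "type": "array",
  "items": {
    "type": "object",
    "required": ["raw_composition", "canonical", "categories", "annotation",
                 "provenance", "tissues", "needs_manual"],
    "properties": {
      "raw_composition": {"type": "string"},
      "canonical": {"type": "string"},
      "categories": {"type": "array", "items": {
        "enum": ["I1", "I2", "C1", "C2", "C3", "C4", "C5", "C6", "UNCLASSIFIED"]
      }},
      "annotation": {"type": "string"},
      "provenance": {"enum": ["machine", "heuristic", "needs_manual"]},
      "tissues": {"type": "array", "items": {"type": "string"}},
      "needs_manual": {"type": "boolean"}
    },
    "additionalProperties": false
  }
}
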