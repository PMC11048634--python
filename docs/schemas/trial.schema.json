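{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "bnburden trial spec",
  "description": "Declarative trial definition: named arms as evidence programs over one network, plus shared evidence applied to every arm.",
  "type": "object",
  "required": ["name", "arms"],
  "properties": {
    "name": {"type": "string"},
    "shared_evidence": {"$ref": "#/$defs/evidenceProgram"},
    "arms": {
      "type": "array",
      "minItems": 2,
      "items": {
        "type": "object",
        "required": ["name"],
        "properties": {
          "name": {"type": "string"},
          "evidence": {"$ref": "#/$defs/evidenceProgram"},
          "endpoints": {
            "type": "array",
            "items": {"type": "array", "prefixItems": [{"type": "string"}, {"type": "string"}]}
          }
        }
      }
    }
  },
  "$defs": {
    "evidenceProgram": {
      "type": "object",
      "properties": {
        "hard": {"type": "object", "additionalProperties": {"type": "string"}},
        "virtual": {"type": "object", "additionalProperties": {"type": "array", "items": {"type": "number", "minimum": 0}}},
        "do": {"type": "object", "additionalProperties": {"oneOf": [{"type": "string"}, {"type": "array", "items": {"type": "number"}}]}},
        "mixture": {
          "type": "array",
          "description": "weights sum to 1; components may not themselves contain mixtures",
          "items": {"type": "array", "prefixItems": [{"type": "number", "minimum": 0}, {"$ref": "#/$defs/evidenceProgram"}]}
        }
      }
    }
  }
}
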