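{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "bnburden network dialect",
  "description": "Discrete Bayesian network with clinical role tags and an optional disability-weight registry. CPT rows enumerate parent-state combinations with the LAST declared parent varying fastest.",
  "type": "object",
  "required": ["format", "version", "nodes"],
  "properties": {
    "format": {"const": "bnburden-network"},
    "version": {"const": 1},
    "metadata": {"type": "object", "description": "free-form provenance: elicitation source, generator, seed, version"},
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "states", "cpt"],
        "properties": {
          "name": {"type": "string", "minLength": 1},
          "states": {"type": "array", "items": {"type": "string"}, "minItems": 2},
          "role": {"enum": ["pretreatment", "intervention", "outcome", "toxicity", "derived"]},
          "parents": {"type": "array", "items": {"type": "string"}},
          "cpt": {
            "type": "array",
            "description": "rows x states; each row a distribution summing to 1 within 1e-9",
            "items": {"type": "array", "items": {"type": "number", "minimum": 0, "maximum": 1}}
          }
        }
      }
    },
    "burden_registry": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["outcome_id", "node", "harm_state", "dw"],
        "properties": {
          "outcome_id": {"type": "string"},
          "node": {"type": "string"},
          "harm_state": {"type": "string"},
          "dw": {"type": "number", "minimum": 0, "maximum": 1},
          "dw_beta": {"type": "array", "items": {"type": "number", "exclusiveMinimum": 0}, "minItems": 2, "maxItems": 2}
        }
      }
    }
  }
}
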