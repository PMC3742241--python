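{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "ConsensusPharmacophore",
  "type": "object",
  "required": ["meta", "features", "excluded_volumes"],
  "properties": {
    "meta": {
      "type": "object",
      "properties": {
        "n_complexes": {"type": "integer", "minimum": 0},
        "threshold": {"type": "number"},
        "provenance": {"type": "array", "items": {"type": "string"}}
      }
    },
    "features": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["id", "kind", "center", "tolerance"],
        "properties": {
          "id": {"type": "string"},
          "kind": {"enum": ["HBD", "HBA", "HYD", "POS", "NEG"]},
          "center": {"type": "array", "items": {"type": "number"},
                     "minItems": 3, "maxItems": 3},
          "tolerance": {"type": "number", "exclusiveMinimum": 0},
          "mandatory": {"type": "boolean"},
          "weight": {"type": "number"}
        }
      }
    },
    "excluded_volumes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["center", "radius"],
        "properties": {
          "center": {"type": "array", "items": {"type": "number"},
                     "minItems": 3, "maxItems": 3},
          "radius": {"type": "number", "exclusiveMinimum": 0},
          "source_residue": {"type": "string"}
        }
      }
    }
  }
}
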