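{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Typed knowledge-graph view document",
  "type": "object",
  "required": ["view", "treatment", "directed", "nodes", "edges"],
  "additionalProperties": false,
  "properties": {
    "view": {"enum": ["categories", "pathways", "targets"]},
    "treatment": {"type": "string", "minLength": 1},
    "directed": {"const": true},
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "type", "label", "layer"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "type": {
            "enum": [
              "treatment", "compound", "category", "action_keyword",
              "global_pathway", "smpdb_pathway", "target",
              "associated_drug", "effect_box", "missing_data"
            ]
          },
          "label": {"type": "string"},
          "layer": {"type": "integer", "minimum": 0}
        }
      }
    },
    "edges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["source", "target", "edge_type"],
        "additionalProperties": false,
        "properties": {
          "source": {"type": "string"},
          "target": {"type": "string"},
          "edge_type": {"type": "string"}
        }
      }
    }
  }
}
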