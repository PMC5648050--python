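{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "ElicitationSet",
  "type": "object",
  "required": ["responses"],
  "properties": {
    "schema_version": {"type": "string"},
    "anchors": {
      "type": ["object", "null"],
      "required": ["open_observed", "evar_observed"],
      "properties": {
        "open_observed": {"type": "number", "minimum": -20, "maximum": 100},
        "evar_observed": {"type": "number", "minimum": -20, "maximum": 100}
      }
    },
    "responses": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["expert_id", "role", "open_missing", "evar_missing", "evar_given_open"],
        "properties": {
          "expert_id": {"type": "string", "minLength": 1},
          "role": {"enum": ["doctor", "nurse", "other"]},
          "venue": {"enum": ["email", "conference", "face_to_face"]},
          "years_band": {"type": "string"},
          "familiarity": {"type": "string"},
          "open_missing": {"$ref": "#/$defs/elicitedNormal"},
          "evar_missing": {"$ref": "#/$defs/elicitedNormal"},
          "evar_given_open": {
            "type": "object",
            "required": ["conditioning_value", "distribution"],
            "properties": {
              "conditioning_value": {"type": "number", "minimum": -20, "maximum": 100},
              "distribution": {"$ref": "#/$defs/elicitedNormal"}
            }
          },
          "correlation_statement": {"enum": ["positive", "zero", "negative", null]},
          "complete": {"type": "boolean"}
        }
      }
    }
  },
  "$defs": {
    "elicitedNormal": {
      "type": "object",
      "required": ["mode", "sd"],
      "properties": {
        "mode": {"type": "number", "minimum": -20, "maximum": 100},
        "sd": {"type": "number", "exclusiveMinimum": 0}
      }
    }
  }
}
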