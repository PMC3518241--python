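{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/rxswitch/kb.schema.json",
  "title": "rxswitch therapeutic-interchange knowledge base",
  "description": "YAML document (validated here in its JSON data model): top-level 'classes' list plus optional 'exclusions'. Conversion factors are stored as per-member equipotent daily doses (target/source dose ratio is derived), which enforces reciprocity and in-class transitivity by construction. No class ATC code may fall under an excluded prefix.",
  "type": "object",
  "required": ["classes"],
  "properties": {
    "exclusions": {
      "type": "object",
      "properties": {
        "atc_prefixes": {
          "type": "array",
          "items": {"type": "string", "pattern": "^[A-Z]([0-9]{2}([A-Z]([A-Z]([0-9]{2})?)?)?)?$"}
        },
        "oral_only": {"type": "boolean"}
      },
      "additionalProperties": false
    },
    "classes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["class_id", "atc_codes", "members"],
        "properties": {
          "class_id": {"type": "string", "minLength": 1},
          "name": {"type": "string"},
          "atc_codes": {
            "type": "array",
            "minItems": 1,
            "items": {"type": "string", "pattern": "^[A-Z][0-9]{2}[A-Z]{2}([0-9]{2})?$"}
          },
          "oral_solid_only": {"type": "boolean"},
          "members": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["parent", "equipotent_daily_dose"],
              "properties": {
                "parent": {"type": "string", "minLength": 1},
                "equipotent_daily_dose": {
                  "description": "indication token -> equipotent daily dose (mg/day or IU/day), strictly positive; at least one entry.",
                  "type": "object",
                  "minProperties": 1,
                  "additionalProperties": {"type": "number", "exclusiveMinimum": 0}
                },
                "notes": {"type": "string"}
              },
              "additionalProperties": false
            }
          }
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false
}
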