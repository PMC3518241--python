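{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/rxswitch/catalogue.schema.json",
  "title": "rxswitch drug-product catalogue",
  "description": "Two equivalent dialects: (a) semicolon-delimited UTF-8 text with a mandatory header row 'product_id;brand_name;ingredients;dosage_form;release;route;atc_codes;indications;on_hdf;divisibility', decimal point (never comma), ingredients as 'parent:amount:unit' joined by '+' for combinations, atc_codes and indications comma-joined, on_hdf as 0/1; (b) a JSON array of records validated by this schema, where list-valued fields may be arrays or the same joined strings.",
  "type": "array",
  "items": {
    "type": "object",
    "required": [
      "product_id",
      "brand_name",
      "ingredients",
      "dosage_form",
      "release",
      "route",
      "atc_codes",
      "indications",
      "on_hdf",
      "divisibility"
    ],
    "properties": {
      "product_id": {"type": "string", "minLength": 1},
      "brand_name": {"type": "string"},
      "ingredients": {
        "description": "Each entry 'name:amount:unit'; amount > 0; unit in mg|microgram|IU; a recognised trailing salt descriptor in the name is split off as informational metadata.",
        "oneOf": [
          {"type": "string", "pattern": "^[^:;+]+:[0-9][0-9./]*:(mg|microgram|IU)(\\+[^:;+]+:[0-9][0-9./]*:(mg|microgram|IU))*$"},
          {
            "type": "array",
            "minItems": 1,
            "items": {"type": "string", "pattern": "^[^:;+]+:[0-9][0-9./]*:(mg|microgram|IU)$"}
          }
        ]
      },
      "dosage_form": {"type": "string", "minLength": 1},
      "release": {"enum": ["immediate", "modified"]},
      "route": {"enum": ["oral", "parenteral", "inhaled", "topical", "other"]},
      "atc_codes": {
        "oneOf": [
          {"type": "string", "pattern": "^([A-Z][0-9]{2}[A-Z]{2}([0-9]{2})?(,[A-Z][0-9]{2}[A-Z]{2}([0-9]{2})?)*)?$"},
          {"type": "array", "items": {"type": "string", "pattern": "^[A-Z][0-9]{2}[A-Z]{2}([0-9]{2})?$"}}
        ]
      },
      "indications": {
        "oneOf": [
          {"type": "string"},
          {"type": "array", "items": {"type": "string"}}
        ]
      },
      "on_hdf": {
        "oneOf": [{"enum": ["0", "1", 0, 1]}, {"type": "boolean"}]
      },
      "divisibility": {"enum": [1, 2, 4, "1", "2", "4"]}
    },
    "additionalProperties": false
  }
}
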