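{
  "$id": "ngffkit:plate.synthetic.schema.json",
  "title": "Synthetic in-repo schema for NGFF v0.4 plate attributes (authored for this package; not the upstream text)",
  "type": "object",
  "required": ["plate"],
  "properties": {
    "plate": {
      "type": "object",
      "required": ["version", "rows", "columns", "wells"],
      "properties": {
        "version": {"const": "0.4"},
        "name": {"type": "string"},
        "field_count": {"type": "integer", "minimum": 1},
        "acquisitions": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["id"],
            "properties": {
              "id": {"type": "integer"},
              "name": {"type": "string"},
              "maximumfieldcount": {"type": "integer"}
            }
          }
        },
        "rows": {
          "type": "array",
          "minItems": 1,
          "items": {"type": "object", "required": ["name"], "properties": {"name": {"type": "string"}}}
        },
        "columns": {
          "type": "array",
          "minItems": 1,
          "items": {"type": "object", "required": ["name"], "properties": {"name": {"type": "string"}}}
        },
        "wells": {
          "type": "array",
          "minItems": 1,
          "items": {
            "type": "object",
            "required": ["path", "rowIndex", "columnIndex"],
            "properties": {
              "path": {"type": "string"},
              "rowIndex": {"type": "integer", "minimum": 0},
              "columnIndex": {"type": "integer", "minimum": 0}
            }
          }
        }
      }
    }
  }
}
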