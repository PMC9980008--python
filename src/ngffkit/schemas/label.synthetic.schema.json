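{
  "$id": "ngffkit:label.synthetic.schema.json",
  "title": "Synthetic in-repo schema for NGFF v0.4 image-label attributes (authored for this package; not the upstream text)",
  "type": "object",
  "required": ["image-label"],
  "properties": {
    "image-label": {
      "type": "object",
      "properties": {
        "version": {"const": "0.4"},
        "colors": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["label-value"],
            "properties": {
              "label-value": {"type": "integer"},
              "rgba": {"type": "array", "minItems": 4, "maxItems": 4, "items": {"type": "integer", "minimum": 0, "maximum": 255}}
            }
          }
        },
        "source": {
          "type": "object",
          "properties": {"image": {"type": "string"}}
        },
        "properties": {
          "type": "array",
          "items": {"type": "object", "required": ["label-value"]}
        }
      }
    }
  }
}
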