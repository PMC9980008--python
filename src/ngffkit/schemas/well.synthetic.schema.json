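{
  "$id": "ngffkit:well.synthetic.schema.json",
  "title": "Synthetic in-repo schema for NGFF v0.4 well attributes (authored for this package; not the upstream text)",
  "type": "object",
  "required": ["well"],
  "properties": {
    "well": {
      "type": "object",
      "required": ["version", "images"],
      "properties": {
        "version": {"const": "0.4"},
        "images": {
          "type": "array",
          "minItems": 1,
          "items": {
            "type": "object",
            "required": ["path"],
            "properties": {
              "path": {"type": "string"},
              "acquisition": {"type": "integer"}
            }
          }
        }
      }
    }
  }
}
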