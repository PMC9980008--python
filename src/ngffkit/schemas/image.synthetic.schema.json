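{
  "$id": "ngffkit:image.synthetic.schema.json",
  "title": "Synthetic in-repo schema for NGFF v0.4 image group attributes (authored for this package; not the upstream text)",
  "type": "object",
  "required": ["multiscales"],
  "properties": {
    "multiscales": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["version", "axes", "datasets"],
        "properties": {
          "version": {"const": "0.4"},
          "name": {"type": "string"},
          "type": {"type": "string"},
          "axes": {
            "type": "array",
            "minItems": 2,
            "maxItems": 5,
            "items": {
              "type": "object",
              "required": ["name", "type"],
              "properties": {
                "name": {"type": "string"},
                "type": {"enum": ["time", "channel", "space"]},
                "unit": {"type": "string"}
              }
            }
          },
          "datasets": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "object",
              "required": ["path", "coordinateTransformations"],
              "properties": {
                "path": {"type": "string"},
                "coordinateTransformations": {
                  "type": "array",
                  "minItems": 1,
                  "items": {
                    "type": "object",
                    "required": ["type"],
                    "properties": {
                      "type": {"enum": ["scale", "translation"]},
                      "scale": {"type": "array", "items": {"type": "number"}},
                      "translation": {"type": "array", "items": {"type": "number"}}
                    }
                  }
                }
              }
            }
          },
          "coordinateTransformations": {"type": "array"}
        }
      }
    }
  }
}
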