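{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "bgcminer sideload annotations",
  "type": "object",
  "required": ["tool", "records"],
  "properties": {
    "tool": {
      "type": "object",
      "required": ["name", "version"],
      "properties": {
        "name": {"type": "string"},
        "version": {"type": "string"}
      }
    },
    "records": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "subregions"],
        "properties": {
          "name": {"type": "string"},
          "subregions": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["start", "end", "label"],
              "properties": {
                "start": {"type": "integer", "minimum": 0},
                "end": {"type": "integer", "minimum": 1},
                "label": {"type": "string"},
                "details": {"type": "object"}
              }
            }
          }
        }
      }
    }
  }
}
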