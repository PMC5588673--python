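{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "RiskAssessment-style detection report",
  "type": "object",
  "required": ["resourceType", "status", "subject", "occurrenceDateTime",
               "extension", "basis", "prediction"],
  "properties": {
    "resourceType": {"const": "RiskAssessment"},
    "status": {"type": "string", "enum": ["final"]},
    "subject": {
      "type": "object",
      "required": ["reference"],
      "properties": {"reference": {"type": "string"}}
    },
    "occurrenceDateTime": {"type": "string"},
    "extension": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["url"],
        "properties": {
          "url": {"type": "string"},
          "valueString": {"type": "string"}
        }
      }
    },
    "basis": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["kpi", "datatype", "value"],
        "properties": {
          "kpi": {"type": "string"},
          "datatype": {"type": "string",
                       "enum": ["boolean", "text", "date", "number"]}
        }
      }
    },
    "prediction": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["outcome", "probabilityRange", "rationale", "extension"],
        "properties": {
          "outcome": {
            "type": "object",
            "required": ["text"],
            "properties": {"text": {"type": "string"}}
          },
          "probabilityRange": {
            "type": "object",
            "required": ["low", "high"],
            "properties": {
              "low": {"type": "string", "pattern": "-?\\d+(\\.\\d+)?"},
              "high": {"type": "string", "pattern": "-?\\d+(\\.\\d+)?"}
            }
          },
          "rationale": {"type": "string"},
          "extension": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["url"],
              "properties": {
                "url": {"type": "string"},
                "valueString": {"type": "string"},
                "valueExplanations": {
                  "type": "array",
                  "items": {
                    "type": "object",
                    "required": ["conjunctionIndex", "sentence", "literals"],
                    "properties": {
                      "conjunctionIndex": {"type": "integer"},
                      "sentence": {"type": "string"},
                      "literals": {
                        "type": "array",
                        "items": {
                          "type": "object",
                          "required": ["condition", "kpi", "range", "positive"],
                          "properties": {
                            "condition": {"type": "string"},
                            "kpi": {"type": "string"},
                            "range": {"type": "string"},
                            "positive": {"type": "boolean"}
                          }
                        }
                      }
                    }
                  }
                }
              }
            }
          }
        }
      }
    }
  }
}
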