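{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "cmekit reaction network definition",
  "type": "object",
  "required": ["species", "reactions"],
  "properties": {
    "name": {"type": "string"},
    "compartments": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name"],
        "properties": {
          "name": {"type": "string"},
          "volume": {"type": "number", "exclusiveMinimum": 0}
        }
      }
    },
    "species": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["name"],
        "properties": {
          "name": {"type": "string"},
          "compartment": {"type": "string"},
          "initial_amount": {"type": "integer", "minimum": 0},
          "abundance_class": {"enum": ["low_copy", "high_copy", "auto"]}
        }
      }
    },
    "parameters": {
      "type": "object",
      "additionalProperties": {"type": "number"}
    },
    "reactions": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["propensity"],
        "properties": {
          "name": {"type": "string"},
          "reactants": {"type": "object", "additionalProperties": {"type": "integer", "minimum": 1}},
          "products": {"type": "object", "additionalProperties": {"type": "integer", "minimum": 1}},
          "propensity": {"type": "string"},
          "kinetics": {"enum": ["mass_action", "general"]},
          "delay": {"type": "number", "minimum": 0}
        }
      }
    },
    "inputs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "expression"],
        "properties": {
          "name": {"type": "string"},
          "expression": {"type": "string"}
        }
      }
    },
    "observables": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "expression"],
        "properties": {
          "name": {"type": "string"},
          "expression": {"type": "string"}
        }
      }
    }
  }
}
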