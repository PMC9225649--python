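{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "crswnp-cea model configuration",
  "description": "Complete parameter set for the decision-tree + Markov cost-utility model. All monetary values are EUR; probabilities and utilities lie in [0, 1]. Missing sections are filled from the packaged defaults at load time. Every numeric parameter must carry a provenance tag in the provenance map.",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "demographics": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "start_age": {"type": "number", "exclusiveMinimum": 18},
        "male_fraction": {"type": "number", "minimum": 0, "maximum": 1}
      }
    },
    "response": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "p_resp_wk24_dup": {"$ref": "#/$defs/probability"},
        "p_resp_wk24_bsc": {"$ref": "#/$defs/probability"},
        "p_resp_wk52_given_wk24_dup": {"$ref": "#/$defs/probability"},
        "p_resp_wk52_given_wk24_bsc": {"$ref": "#/$defs/probability"},
        "provenance_note": {"type": "string"}
      }
    },
    "sustained": {
      "type": "object",
      "additionalProperties": false,
      "properties": {"annual_p_sustain": {"$ref": "#/$defs/probability"}}
    },
    "surgery_access": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "p_ineligible": {"$ref": "#/$defs/probability"},
        "max_surgery_age": {"type": "number", "minimum": 0},
        "annual_p_surgery": {"$ref": "#/$defs/probability"},
        "p_postop_to_uncontrolled": {"$ref": "#/$defs/probability"},
        "p_surgery_to_postop_controlled": {"$ref": "#/$defs/probability"}
      }
    },
    "tree_utilities": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "u_baseline": {"$ref": "#/$defs/utility"},
        "u_wk12_24_dup": {"$ref": "#/$defs/utility"},
        "u_wk12_24_bsc": {"$ref": "#/$defs/utility"},
        "u_wk24plus_responder": {"$ref": "#/$defs/utility"},
        "u_wk24plus_nonresponder": {"$ref": "#/$defs/utility"}
      }
    },
    "markov_utilities": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "u_controlled": {"$ref": "#/$defs/utility"},
        "u_inadequate": {"$ref": "#/$defs/utility"},
        "u_surgery": {"$ref": "#/$defs/utility"},
        "u_postop_controlled": {"$ref": "#/$defs/utility"},
        "u_postop_uncontrolled": {"$ref": "#/$defs/utility"},
        "u_death": {"$ref": "#/$defs/utility"}
      }
    },
    "tree_costs": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "therapy_responder_h1": {"$ref": "#/$defs/money"},
        "therapy_responder_h2": {"$ref": "#/$defs/money"},
        "medical_responder_h1": {"$ref": "#/$defs/money"},
        "medical_responder_h2": {"$ref": "#/$defs/money"},
        "therapy_nonresponder_h1": {"$ref": "#/$defs/money"},
        "therapy_nonresponder_h2": {"$ref": "#/$defs/money"},
        "medical_nonresponder_h1": {"$ref": "#/$defs/money"},
        "medical_nonresponder_h2": {"$ref": "#/$defs/money"}
      }
    },
    "markov_state_costs": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "controlled": {"$ref": "#/$defs/money"},
        "inadequate": {"$ref": "#/$defs/money"},
        "postop_controlled": {"$ref": "#/$defs/money"},
        "postop_uncontrolled": {"$ref": "#/$defs/money"},
        "death": {"$ref": "#/$defs/money"}
      }
    },
    "drug": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "price_per_administration": {
          "oneOf": [{"$ref": "#/$defs/money"}, {"type": "null"}],
          "description": "Required for any run of the intervention arm; no default exists because the net price is not public."
        },
        "administrations_per_year": {"type": "integer", "exclusiveMinimum": 0},
        "compliance": {"$ref": "#/$defs/probability"},
        "bsc_acquisition_cost": {"$ref": "#/$defs/money"},
        "administration_cost": {"$ref": "#/$defs/money"}
      }
    },
    "ae_items": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["name", "rate_dup", "rate_bsc", "unit_cost"],
        "properties": {
          "name": {"type": "string"},
          "rate_dup": {"type": "number", "minimum": 0},
          "rate_bsc": {"type": "number", "minimum": 0},
          "unit_cost": {"$ref": "#/$defs/money"}
        }
      }
    },
    "surgery_costs": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "ct_scan": {"$ref": "#/$defs/money"},
        "procedure": {"$ref": "#/$defs/money"},
        "annual_followup": {"$ref": "#/$defs/money"},
        "followup_visits_per_year": {"type": "integer", "minimum": 0},
        "visit_tariff": {"$ref": "#/$defs/money"}
      }
    },
    "indirect": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "eur_per_hour": {"$ref": "#/$defs/money"},
        "hours_per_day": {"type": "number", "minimum": 0},
        "workdays_lost_per_year_by_state": {
          "type": "object",
          "additionalProperties": {"type": "number", "minimum": 0}
        }
      }
    },
    "econ": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "discount_rate_costs": {"type": "number", "minimum": 0, "exclusiveMaximum": 1},
        "discount_rate_effects": {"type": "number", "minimum": 0, "exclusiveMaximum": 1},
        "horizon_max_age": {"type": "number"},
        "perspective": {"enum": ["NHS", "societal"]},
        "wtp_grid": {"type": "array", "items": {"type": "number", "minimum": 0}}
      }
    },
    "switches": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "nr52_responder_utility": {"type": "boolean"},
        "tree_mortality": {"type": "boolean"},
        "half_cycle_correction": {"type": "boolean"},
        "ae_costs_lifetime": {"type": "boolean"},
        "postop_followup_separate": {"type": "boolean"}
      }
    },
    "life_table": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "kind": {"enum": ["gompertz_makeham", "csv"]},
        "path": {"oneOf": [{"type": "string"}, {"type": "null"}]},
        "makeham_a": {"type": "number", "minimum": 0},
        "gompertz_b": {"type": "number", "exclusiveMinimum": 0},
        "gompertz_c": {"type": "number", "exclusiveMinimum": 0},
        "min_age": {"type": "integer", "minimum": 0},
        "max_age": {"type": "integer", "exclusiveMinimum": 0}
      }
    },
    "seed": {"type": "integer"},
    "provenance": {
      "type": "object",
      "additionalProperties": {
        "enum": ["paper-table", "paper-text", "figure-only-placeholder", "synthetic", "derived", "user"]
      }
    }
  },
  "$defs": {
    "probability": {"type": "number", "minimum": 0, "maximum": 1},
    "utility": {"type": "number", "minimum": 0, "maximum": 1},
    "money": {"type": "number", "minimum": 0}
  }
}
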