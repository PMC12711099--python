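{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "copdcem ParameterSet",
  "type": "object",
  "$defs": {
    "probability": {"type": "number", "minimum": 0, "maximum": 1},
    "nonneg": {"type": "number", "minimum": 0},
    "by_severity": {
      "type": "object",
      "properties": {
        "moderate": {"type": "number"},
        "severe": {"type": "number"},
        "very_severe": {"type": "number"}
      },
      "required": ["moderate", "severe", "very_severe"]
    },
    "progression": {
      "type": "object",
      "properties": {
        "mod_to_sev": {"$ref": "#/$defs/probability"},
        "sev_to_vsev": {"$ref": "#/$defs/probability"}
      },
      "required": ["mod_to_sev", "sev_to_vsev"]
    },
    "per_arm": {
      "type": "object",
      "additionalProperties": {"type": "number"}
    }
  },
  "properties": {
    "baseline_distribution": {"$ref": "#/$defs/by_severity"},
    "transition_probs": {
      "type": "object",
      "properties": {
        "trial_year1": {"$ref": "#/$defs/progression"},
        "no_exac_history": {"$ref": "#/$defs/progression"},
        "ffumecvi_rr": {"type": "number", "exclusiveMinimum": 0}
      }
    },
    "exacerbation_probs": {
      "type": "object",
      "properties": {
        "moderate_monthly": {"$ref": "#/$defs/by_severity"},
        "severe_monthly": {"$ref": "#/$defs/by_severity"},
        "ffumecvi_rr_moderate": {"type": "number", "exclusiveMinimum": 0},
        "ffumecvi_rr_severe": {"type": "number", "exclusiveMinimum": 0},
        "post_exac_multiplier": {"type": "number", "exclusiveMinimum": 0}
      }
    },
    "mortality_params": {
      "type": "object",
      "properties": {
        "severity_rr": {"$ref": "#/$defs/by_severity"},
        "post_exac_rr_moderate": {"type": "number", "exclusiveMinimum": 0},
        "post_exac_rr_severe": {"type": "number", "exclusiveMinimum": 0},
        "severe_exac_mortality": {"$ref": "#/$defs/probability"},
        "severe_exac_mortality_year1": {"$ref": "#/$defs/probability"},
        "constant_monthly_death": {"$ref": "#/$defs/per_arm"}
      }
    },
    "utilities": {
      "type": "object",
      "properties": {
        "severity_utility": {"$ref": "#/$defs/by_severity"},
        "moderate_exac_decrement": {"$ref": "#/$defs/nonneg"},
        "severe_exac_decrement": {"$ref": "#/$defs/nonneg"},
        "death_utility": {"type": "number"}
      }
    },
    "costs": {
      "type": "object",
      "properties": {
        "disease_mgmt_monthly": {"$ref": "#/$defs/by_severity"},
        "moderate_exac_event": {"$ref": "#/$defs/nonneg"},
        "severe_exac_event": {"$ref": "#/$defs/nonneg"},
        "acquisition_monthly": {"$ref": "#/$defs/per_arm"},
        "rescue_monthly": {"$ref": "#/$defs/nonneg"},
        "ae_one_time": {"$ref": "#/$defs/per_arm"},
        "subsequent_monthly": {"$ref": "#/$defs/nonneg"},
        "end_of_life_hospital": {"$ref": "#/$defs/nonneg"},
        "end_of_life_by_setting": {"$ref": "#/$defs/per_arm"},
        "end_of_life_setting_mix": {"$ref": "#/$defs/per_arm"}
      }
    },
    "discontinuation": {
      "type": "object",
      "properties": {
        "first_year_monthly": {"$ref": "#/$defs/per_arm"},
        "post_year1_monthly": {"$ref": "#/$defs/probability"}
      }
    },
    "discount_rate_costs": {"$ref": "#/$defs/nonneg"},
    "discount_rate_outcomes": {"$ref": "#/$defs/nonneg"},
    "wtp_threshold": {"$ref": "#/$defs/nonneg"},
    "baseline_age": {"type": "integer", "minimum": 18},
    "proportion_female": {"$ref": "#/$defs/probability"},
    "horizon_months": {"type": "integer", "minimum": 1},
    "mortality_mode": {"enum": ["km_curve", "constant"]},
    "half_cycle_correction": {"type": "boolean"},
    "lump_sum_decrements": {"type": "boolean"}
  }
}
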