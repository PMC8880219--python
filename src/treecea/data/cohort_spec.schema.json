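{
  "$defs": {
    "_ArmCohortCfg": {
      "additionalProperties": false,
      "properties": {
        "name": {
          "title": "Name",
          "type": "string"
        },
        "n": {
          "minimum": 2,
          "title": "N",
          "type": "integer"
        },
        "p_death": {
          "maximum": 1,
          "minimum": 0,
          "title": "P Death",
          "type": "number"
        },
        "outpatient": {
          "$ref": "#/$defs/_StatCfg"
        },
        "inpatient": {
          "$ref": "#/$defs/_StatCfg"
        },
        "utility": {
          "$ref": "#/$defs/_RangeCfg"
        },
        "survival_days": {
          "$ref": "#/$defs/_StatCfg"
        },
        "decedent_cost_ratio": {
          "default": 1.0,
          "exclusiveMinimum": 0,
          "title": "Decedent Cost Ratio",
          "type": "number"
        }
      },
      "required": [
        "name",
        "n",
        "p_death",
        "outpatient",
        "inpatient",
        "utility",
        "survival_days"
      ],
      "title": "_ArmCohortCfg",
      "type": "object"
    },
    "_RangeCfg": {
      "additionalProperties": false,
      "properties": {
        "low": {
          "maximum": 1,
          "minimum": 0,
          "title": "Low",
          "type": "number"
        },
        "high": {
          "maximum": 1,
          "minimum": 0,
          "title": "High",
          "type": "number"
        }
      },
      "required": [
        "low",
        "high"
      ],
      "title": "_RangeCfg",
      "type": "object"
    },
    "_StatCfg": {
      "additionalProperties": false,
      "properties": {
        "mean": {
          "exclusiveMinimum": 0,
          "title": "Mean",
          "type": "number"
        },
        "sd": {
          "exclusiveMinimum": 0,
          "title": "Sd",
          "type": "number"
        }
      },
      "required": [
        "mean",
        "sd"
      ],
      "title": "_StatCfg",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "properties": {
    "arms": {
      "items": {
        "$ref": "#/$defs/_ArmCohortCfg"
      },
      "minItems": 1,
      "title": "Arms",
      "type": "array"
    }
  },
  "required": [
    "arms"
  ],
  "title": "_CohortCfg",
  "type": "object"
}
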