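{
  "$defs": {
    "_ArmCfg": {
      "additionalProperties": false,
      "properties": {
        "name": {
          "title": "Name",
          "type": "string"
        },
        "n_patients": {
          "minimum": 1,
          "title": "N Patients",
          "type": "integer"
        },
        "p_survive": {
          "$ref": "#/$defs/_DistCfg"
        },
        "branches": {
          "$ref": "#/$defs/_BranchesCfg"
        },
        "utility": {
          "anyOf": [
            {
              "$ref": "#/$defs/_UtilityCfg"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        },
        "life_years": {
          "anyOf": [
            {
              "minimum": 0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Life Years"
        },
        "deaths_full_followup": {
          "anyOf": [
            {
              "minimum": 0,
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Deaths Full Followup"
        }
      },
      "required": [
        "name",
        "n_patients",
        "p_survive",
        "branches"
      ],
      "title": "_ArmCfg",
      "type": "object"
    },
    "_BranchCfg": {
      "additionalProperties": false,
      "properties": {
        "cost": {
          "$ref": "#/$defs/_DistCfg"
        },
        "qaly": {
          "$ref": "#/$defs/_DistCfg"
        }
      },
      "required": [
        "cost",
        "qaly"
      ],
      "title": "_BranchCfg",
      "type": "object"
    },
    "_BranchesCfg": {
      "additionalProperties": false,
      "properties": {
        "survive": {
          "$ref": "#/$defs/_BranchCfg"
        },
        "death": {
          "$ref": "#/$defs/_BranchCfg"
        }
      },
      "required": [
        "survive",
        "death"
      ],
      "title": "_BranchesCfg",
      "type": "object"
    },
    "_DistCfg": {
      "additionalProperties": false,
      "properties": {
        "family": {
          "default": "gamma",
          "enum": [
            "beta",
            "gamma",
            "fixed"
          ],
          "title": "Family",
          "type": "string"
        },
        "central": {
          "title": "Central",
          "type": "number"
        },
        "range": {
          "anyOf": [
            {
              "maxItems": 2,
              "minItems": 2,
              "prefixItems": [
                {
                  "type": "number"
                },
                {
                  "type": "number"
                }
              ],
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Range"
        },
        "sd": {
          "anyOf": [
            {
              "exclusiveMinimum": 0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Sd"
        }
      },
      "required": [
        "central"
      ],
      "title": "_DistCfg",
      "type": "object"
    },
    "_MoneyCfg": {
      "additionalProperties": false,
      "properties": {
        "amount": {
          "title": "Amount",
          "type": "number"
        },
        "currency": {
          "default": "TWD",
          "enum": [
            "TWD",
            "USD"
          ],
          "title": "Currency",
          "type": "string"
        },
        "price_year": {
          "default": 2018,
          "title": "Price Year",
          "type": "integer"
        }
      },
      "required": [
        "amount"
      ],
      "title": "_MoneyCfg",
      "type": "object"
    },
    "_SettingsCfg": {
      "additionalProperties": false,
      "properties": {
        "wtp_threshold": {
          "$ref": "#/$defs/_MoneyCfg"
        },
        "exchange_rate": {
          "exclusiveMinimum": 0,
          "title": "Exchange Rate",
          "type": "number"
        },
        "discount_rate": {
          "default": 0.03,
          "exclusiveMaximum": 1,
          "minimum": 0,
          "title": "Discount Rate",
          "type": "number"
        },
        "n_replications": {
          "default": 1000,
          "minimum": 1,
          "title": "N Replications",
          "type": "integer"
        },
        "rng_seed": {
          "default": 0,
          "title": "Rng Seed",
          "type": "integer"
        },
        "wtp_grid": {
          "$ref": "#/$defs/_WtpGridCfg",
          "default": {
            "max_multiple": 3.0,
            "n_points": 41
          }
        }
      },
      "required": [
        "wtp_threshold",
        "exchange_rate"
      ],
      "title": "_SettingsCfg",
      "type": "object"
    },
    "_UtilityCfg": {
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
      "title": "_UtilityCfg",
      "type": "object"
    },
    "_WtpGridCfg": {
      "additionalProperties": false,
      "properties": {
        "max_multiple": {
          "default": 3.0,
          "exclusiveMinimum": 0,
          "title": "Max Multiple",
          "type": "number"
        },
        "n_points": {
          "default": 41,
          "minimum": 2,
          "title": "N Points",
          "type": "integer"
        }
      },
      "title": "_WtpGridCfg",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "properties": {
    "arms": {
      "items": {
        "$ref": "#/$defs/_ArmCfg"
      },
      "minItems": 1,
      "title": "Arms",
      "type": "array"
    },
    "settings": {
      "$ref": "#/$defs/_SettingsCfg"
    }
  },
  "required": [
    "arms",
    "settings"
  ],
  "title": "_ConfigCfg",
  "type": "object"
}
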