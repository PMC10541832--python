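{
  "$defs": {
    "CalibrationModel": {
      "additionalProperties": false,
      "properties": {
        "is_calibrated": {
          "default": true,
          "title": "Is Calibrated",
          "type": "boolean"
        },
        "mm_per_pixel": {
          "exclusiveMinimum": 0,
          "title": "Mm Per Pixel",
          "type": "number"
        }
      },
      "required": [
        "mm_per_pixel"
      ],
      "title": "CalibrationModel",
      "type": "object"
    },
    "HingesModel": {
      "additionalProperties": false,
      "properties": {
        "femoral": {
          "anyOf": [
            {
              "$ref": "#/$defs/PointModel"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        },
        "tibial": {
          "anyOf": [
            {
              "$ref": "#/$defs/PointModel"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        }
      },
      "title": "HingesModel",
      "type": "object"
    },
    "PlanOverridesModel": {
      "additionalProperties": false,
      "properties": {
        "apply_jlca_adjustment": {
          "anyOf": [
            {
              "type": "boolean"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Apply Jlca Adjustment"
        },
        "femoral_hinge_offset": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Femoral Hinge Offset"
        },
        "nmjl_angle": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Nmjl Angle"
        },
        "osteotomy_obliquity": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Osteotomy Obliquity"
        },
        "target_percent": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Target Percent"
        },
        "tibial_hinge_offset": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Tibial Hinge Offset"
        },
        "tibial_osteotomy_entry_offset": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Tibial Osteotomy Entry Offset"
        },
        "uncalibrated_gap_increment": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Uncalibrated Gap Increment"
        }
      },
      "title": "PlanOverridesModel",
      "type": "object"
    },
    "PointModel": {
      "additionalProperties": false,
      "properties": {
        "x": {
          "title": "X",
          "type": "number"
        },
        "y": {
          "title": "Y",
          "type": "number"
        }
      },
      "required": [
        "x",
        "y"
      ],
      "title": "PointModel",
      "type": "object"
    },
    "PointsModel": {
      "additionalProperties": false,
      "properties": {
        "ankle_center": {
          "$ref": "#/$defs/PointModel"
        },
        "condyle_lateral": {
          "$ref": "#/$defs/PointModel"
        },
        "condyle_medial": {
          "$ref": "#/$defs/PointModel"
        },
        "hip_center": {
          "$ref": "#/$defs/PointModel"
        },
        "plateau_lateral": {
          "$ref": "#/$defs/PointModel"
        },
        "plateau_medial": {
          "$ref": "#/$defs/PointModel"
        }
      },
      "required": [
        "hip_center",
        "plateau_medial",
        "plateau_lateral",
        "condyle_medial",
        "condyle_lateral",
        "ankle_center"
      ],
      "title": "PointsModel",
      "type": "object"
    },
    "SegmentsModel": {
      "additionalProperties": false,
      "properties": {
        "femoral_lateral_cortex": {
          "items": {
            "$ref": "#/$defs/PointModel"
          },
          "maxItems": 2,
          "minItems": 2,
          "title": "Femoral Lateral Cortex",
          "type": "array"
        },
        "femoral_medial_cortex": {
          "items": {
            "$ref": "#/$defs/PointModel"
          },
          "maxItems": 2,
          "minItems": 2,
          "title": "Femoral Medial Cortex",
          "type": "array"
        },
        "tibial_lateral_cortex": {
          "items": {
            "$ref": "#/$defs/PointModel"
          },
          "maxItems": 2,
          "minItems": 2,
          "title": "Tibial Lateral Cortex",
          "type": "array"
        },
        "tibial_medial_cortex": {
          "items": {
            "$ref": "#/$defs/PointModel"
          },
          "maxItems": 2,
          "minItems": 2,
          "title": "Tibial Medial Cortex",
          "type": "array"
        }
      },
      "required": [
        "femoral_medial_cortex",
        "femoral_lateral_cortex",
        "tibial_medial_cortex",
        "tibial_lateral_cortex"
      ],
      "title": "SegmentsModel",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "properties": {
    "calibration": {
      "$ref": "#/$defs/CalibrationModel"
    },
    "hinges": {
      "anyOf": [
        {
          "$ref": "#/$defs/HingesModel"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "patient_id": {
      "title": "Patient Id",
      "type": "string"
    },
    "plan_overrides": {
      "anyOf": [
        {
          "$ref": "#/$defs/PlanOverridesModel"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "points": {
      "$ref": "#/$defs/PointsModel"
    },
    "schema_version": {
      "title": "Schema Version",
      "type": "integer"
    },
    "segments": {
      "$ref": "#/$defs/SegmentsModel"
    },
    "side": {
      "title": "Side",
      "type": "string"
    }
  },
  "required": [
    "schema_version",
    "patient_id",
    "side",
    "calibration",
    "points",
    "segments"
  ],
  "title": "LandmarkFileV1",
  "type": "object"
}
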