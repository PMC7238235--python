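{
  "$defs": {
    "FeederGeometry": {
      "additionalProperties": false,
      "description": "Paddle-wheel geometry and powder hold-up of a feed frame.",
      "properties": {
        "paddle_diameter": {
          "description": "paddle wheel diameter d_p (m)",
          "exclusiveMinimum": 0,
          "title": "Paddle Diameter",
          "type": "number"
        },
        "n_spokes": {
          "description": "number of paddle spokes k_s",
          "minimum": 1,
          "title": "N Spokes",
          "type": "integer"
        },
        "clearance": {
          "description": "spoke-to-base clearance c (m)",
          "exclusiveMinimum": 0,
          "title": "Clearance",
          "type": "number"
        },
        "holdup_mass": {
          "description": "powder mass in the feed frame m (kg)",
          "exclusiveMinimum": 0,
          "title": "Holdup Mass",
          "type": "number"
        },
        "feed_volume": {
          "description": "feed system volume V_R (m^3)",
          "exclusiveMinimum": 0,
          "title": "Feed Volume",
          "type": "number"
        },
        "bulk_density": {
          "description": "powder bulk density rho_b (kg/m^3)",
          "exclusiveMinimum": 0,
          "title": "Bulk Density",
          "type": "number"
        }
      },
      "required": [
        "paddle_diameter",
        "n_spokes",
        "clearance",
        "holdup_mass",
        "feed_volume",
        "bulk_density"
      ],
      "title": "FeederGeometry",
      "type": "object"
    },
    "PressGeometry": {
      "additionalProperties": false,
      "description": "Turret, compression-roller and punch-head geometry of a (simulated) press.\n\n``die_spacing_angle`` is the angular spacing of the *installed* die set\n(360deg / n_dies for an evenly under-tooled turret); ``fill_angle`` is the\nangle the feed-frame window occupies on the pitch circle.",
      "properties": {
        "name": {
          "title": "Name",
          "type": "string"
        },
        "pitch_circle_diameter": {
          "description": "turret pitch circle diameter (m)",
          "exclusiveMinimum": 0,
          "title": "Pitch Circle Diameter",
          "type": "number"
        },
        "n_dies": {
          "description": "number of installed dies k_d",
          "minimum": 1,
          "title": "N Dies",
          "type": "integer"
        },
        "roller_diameter": {
          "description": "compression roller diameter (m)",
          "exclusiveMinimum": 0,
          "title": "Roller Diameter",
          "type": "number"
        },
        "head_flat_length": {
          "description": "punch head flat length l_f (m)",
          "exclusiveMinimum": 0,
          "title": "Head Flat Length",
          "type": "number"
        },
        "head_radius": {
          "description": "punch head curvature radius r_h (m)",
          "exclusiveMinimum": 0,
          "title": "Head Radius",
          "type": "number"
        },
        "fill_angle": {
          "description": "feeder fill angle phi_fill (deg)",
          "exclusiveMinimum": 0,
          "maximum": 360,
          "title": "Fill Angle",
          "type": "number"
        },
        "die_spacing_angle": {
          "description": "die spacing angle phi_dies (deg)",
          "exclusiveMinimum": 0,
          "maximum": 360,
          "title": "Die Spacing Angle",
          "type": "number"
        }
      },
      "required": [
        "name",
        "pitch_circle_diameter",
        "n_dies",
        "roller_diameter",
        "head_flat_length",
        "head_radius",
        "fill_angle",
        "die_spacing_angle"
      ],
      "title": "PressGeometry",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "A complete machine definition: press geometry, feeder, and machine kind.",
  "properties": {
    "press": {
      "$ref": "#/$defs/PressGeometry"
    },
    "feeder": {
      "$ref": "#/$defs/FeederGeometry"
    },
    "kind": {
      "enum": [
        "rotary_press",
        "compaction_simulator"
      ],
      "title": "Kind",
      "type": "string"
    },
    "provenance": {
      "anyOf": [
        {
          "additionalProperties": {
            "type": "string"
          },
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "description": "per-field data provenance notes (e.g. 'placeholder', 'calibrated')",
      "title": "Provenance"
    }
  },
  "required": [
    "press",
    "feeder",
    "kind"
  ],
  "title": "MachineFixture",
  "type": "object"
}
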