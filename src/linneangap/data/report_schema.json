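{
  "type": "object",
  "required": ["rates", "baseline_rate", "tables", "authors_per_article",
               "breakpoint", "richness_estimates", "budget", "scenarios",
               "provenance"],
  "properties": {
    "rates": {
      "type": "object",
      "required": ["species_per_year", "species_per_article", "articles_per_author", "ranges"],
      "properties": {
        "species_per_year": {"type": "number"},
        "species_per_article": {"type": "number"},
        "articles_per_author": {"type": "number"},
        "ranges": {"type": "object", "required": [], "properties": {}}
      }
    },
    "baseline_rate": {"type": "number"},
    "tables": {"type": "object", "required": [], "properties": {}},
    "authors_per_article": {"type": "object", "required": [], "properties": {}},
    "breakpoint": {
      "type": "object",
      "required": ["breakpoint_year", "cumulative_at_breakpoint", "pre_model",
                   "post_model", "sse_pre", "sse_post", "sse_total",
                   "coordinate_convention"],
      "properties": {
        "breakpoint_year": {"type": "integer"},
        "cumulative_at_breakpoint": {"type": "integer"},
        "pre_model": {"type": "array", "items": {"type": "number"}},
        "post_model": {"type": "array", "items": {"type": "number"}},
        "sse_pre": {"type": "number"},
        "sse_post": {"type": "number"},
        "sse_total": {"type": "number"},
        "coordinate_convention": {"type": "string"}
      }
    },
    "richness_estimates": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["estimator", "estimate"],
        "properties": {
          "estimator": {"type": "string"},
          "estimate": {"type": "number"}
        }
      }
    },
    "budget": {
      "type": "object",
      "required": ["K_total", "described_total", "remaining", "remaining_fraction"],
      "properties": {
        "K_total": {"type": "number"},
        "described_total": {"type": "integer"},
        "remaining": {"type": "number"},
        "remaining_fraction": {"type": "number"}
      }
    },
    "scenarios": {
      "type": "object",
      "required": ["n0_mode", "selected", "scenarios"],
      "properties": {
        "n0_mode": {"type": "string"},
        "selected": {"type": "integer"},
        "scenarios": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["r", "K", "N0", "t0", "threshold_fraction",
                         "completion_year", "sigmoidicity"],
            "properties": {
              "r": {"type": "number"},
              "K": {"type": "number"},
              "N0": {"type": "number"},
              "t0": {"type": "number"},
              "threshold_fraction": {"type": "number"},
              "completion_year": {"type": "number"},
              "sigmoidicity": {"type": "number"}
            }
          }
        }
      }
    },
    "provenance": {
      "type": "object",
      "required": ["package", "version", "config"],
      "properties": {
        "package": {"type": "string"},
        "version": {"type": "string"},
        "config": {"type": "object", "required": [], "properties": {}}
      }
    }
  }
}
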