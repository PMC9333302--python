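{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "reproscore run report",
  "type": "object",
  "required": [
    "dataset",
    "config",
    "n_biomarkers_full",
    "estimates",
    "seed",
    "timestamp",
    "version"
  ],
  "properties": {
    "dataset": {
      "type": "object",
      "required": ["n", "n_plus", "n_minus", "r", "feature_kind", "positive_label"],
      "properties": {
        "n": {"type": "integer", "minimum": 2},
        "n_plus": {"type": "integer", "minimum": 1},
        "n_minus": {"type": "integer", "minimum": 1},
        "r": {"type": "integer", "minimum": 1},
        "feature_kind": {"enum": ["continuous", "genotype"]},
        "positive_label": {"type": "string"}
      }
    },
    "config": {
      "type": "object",
      "required": ["test", "alpha", "mcc"],
      "properties": {
        "test": {"enum": ["t", "welch"]},
        "alpha": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
        "mcc": {"enum": ["bh", "bonferroni", "none"]}
      }
    },
    "n_biomarkers_full": {"type": "integer", "minimum": 0},
    "estimates": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["method", "k", "mean", "sd", "seed", "per_iteration"],
        "properties": {
          "method": {"type": "string"},
          "k": {"type": "integer", "minimum": 1},
          "mean": {"type": "number", "minimum": 0, "maximum": 1},
          "sd": {"type": "number", "minimum": 0},
          "seed": {"type": "integer"},
          "subset_size": {"type": "integer", "minimum": 4},
          "per_iteration": {
            "type": "array",
            "items": {"type": "number", "minimum": 0, "maximum": 1}
          }
        }
      }
    },
    "seed": {"type": "integer"},
    "timestamp": {"type": "string"},
    "version": {"type": "string"}
  }
}
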