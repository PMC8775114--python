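{
  "description": "Reported reference values for ground-truth-diagnosis (Naive GT) prioritization on the two test partitions; used by the reproduce command for side-by-side comparison.",
  "test1": {
    "accuracy": 82.53,
    "weighted_f1": 81.81,
    "macro_f1": 56.40,
    "per_class": {
      "HP": {"sensitivity": 53.66, "precision": 70.97, "f1": 61.11},
      "P": {"sensitivity": 15.71, "precision": 18.03, "f1": 16.79},
      "N": {"sensitivity": 92.81, "precision": 89.81, "f1": 91.29}
    },
    "hp_correct": 22
  },
  "test2": {
    "accuracy": 56.25,
    "weighted_f1": 51.02,
    "macro_f1": 51.81,
    "per_class": {
      "HP": {"sensitivity": 53.66, "precision": 78.57, "f1": 63.77},
      "P": {"sensitivity": 15.71, "precision": 37.93, "f1": 22.22},
      "N": {"sensitivity": 92.59, "precision": 55.56, "f1": 69.44}
    }
  }
}
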