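{
  "version": 1,
  "comment": "Reading convention for the published SUM159/SUM149 rate table. The table's column headers are not machine-readable in the available sources, so the assignment of the nine printed columns to the three growth rates and six directed transitions is fixed by enumeration: of all 4320 candidate assignments, this one minimises (uniquely, by a factor of two over the runner-up) the joint L1 distance between the models' stationary compositions and the published equilibrium proportions of the two lines.",
  "labels": ["stem", "basal", "luminal"],
  "growth_columns": ["luminal", "stem", "basal"],
  "transition_columns": [
    ["luminal", "stem"],
    ["luminal", "basal"],
    ["basal", "luminal"],
    ["basal", "stem"],
    ["stem", "luminal"],
    ["stem", "basal"]
  ],
  "rows": {
    "SUM159": {
      "growth": [0.73, 0.69, 0.85],
      "transitions": [0.04, 0.42, 0.0, 0.012, 0.14, 0.33]
    },
    "SUM149": {
      "growth": [0.95, 0.69, 0.91],
      "transitions": [0.03, 0.0, 0.02, 0.01, 0.3, 0.05]
    }
  },
  "reported_compositions": {
    "SUM159": {"stem": 0.019, "basal": 0.973, "luminal": 0.0062},
    "SUM149": {"stem": 0.039, "basal": 0.033, "luminal": 0.928}
  }
}
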