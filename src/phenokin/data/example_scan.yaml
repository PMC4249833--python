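# Example grid-scan specification for a three-phenotype sorting experiment.
#
# Growth rates are held fixed: subpopulation fractions are invariant under a
# uniform shift of all growth rates, so composition data alone cannot pin
# them down (supply total-count fold changes if you need absolute growth).
# All six directed transition rates are scanned on a coarse grid; tighten
# the ranges around the first optimum for a refinement pass (e.g. min/max
# +-0.05 around the best value with step 0.01).
labels: [stem, basal, luminal]
params:
  "g:stem": 0.69
  "g:basal": 0.85
  "g:luminal": 0.73
  "k:stem->basal": {min: 0.0, max: 1.0, step: 0.1}
  "k:stem->luminal": {min: 0.0, max: 1.0, step: 0.1}
  "k:basal->stem": {min: 0.0, max: 1.0, step: 0.1}
  "k:basal->luminal": {min: 0.0, max: 1.0, step: 0.1}
  "k:luminal->stem": {min: 0.0, max: 1.0, step: 0.1}
  "k:luminal->basal": {min: 0.0, max: 1.0, step: 0.1}
feasibility:
  eigen_sign: positive      # require three-way coexistent growth
  require_survivable: false
objective: sse
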