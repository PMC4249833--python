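# SUM159 growth-transition model (rates in 1/day) under the
# column convention recorded in sum_rate_mapping.json
labels:
- stem
- basal
- luminal
growth:
  stem: 0.69
  basal: 0.85
  luminal: 0.73
transitions:
  stem->basal: 0.33
  stem->luminal: 0.14
  basal->stem: 0.012
  luminal->stem: 0.04
  luminal->basal: 0.42
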