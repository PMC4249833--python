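# SUM149 growth-transition model (rates in 1/day) under the
# column convention recorded in sum_rate_mapping.json
labels:
- stem
- basal
- luminal
growth:
  stem: 0.69
  basal: 0.91
  luminal: 0.95
transitions:
  stem->basal: 0.05
  stem->luminal: 0.3
  basal->stem: 0.01
  basal->luminal: 0.02
  luminal->stem: 0.03
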