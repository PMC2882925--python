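# colonyca-config-v1
# Reference rimmed-colony run: printed reference rates, plus sensitivity
# thresholds recovered by the package's grid search (tuned, not printed).
model:
  N: 140
  P: 1.0
  S: 10.0
  A: 5
  O: 0.01
  D: 0.495
  G: 5
  Qlim: 1000.0   # tuned, not printed
  Olim1: 100.0   # tuned, not printed
  Olim2: 220.0   # tuned, not printed
  L: 351
  max_generations: 10000
inoculum:
  kind: point
  positions: [175]
  initial_thickness: 1
output:
  thin: 1
  plot: false
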