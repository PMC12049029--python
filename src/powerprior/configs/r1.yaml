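# Round 1: 63 + 63 patients, 1:1 allocation, no borrowing.
rounds:
  - id: R1
    n_control: 63
    n_experimental: 63
    allocation: [1, 1]
rule:
  margin: 0.15
  certainty: 0.60
grid:
  control_rates: [0.40, 0.50, 0.60]
  differences: [-0.10, 0.0, 0.15, 0.25]
  certainties: [0.50, 0.60, 0.70, 0.80]
  weights: [0.0]
sim:
  reps: 10000
  seed: 20240001
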