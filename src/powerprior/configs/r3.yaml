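# Round 3: 16 control + 63 experimental, 1:4 allocation,
# borrowing the Round-1 (63) and Round-2 (16) control arms.
rounds:
  - id: R1
    n_control: 63
    n_experimental: 63
    allocation: [1, 1]
  - id: R2
    n_control: 16
    n_experimental: 63
    allocation: [1, 4]
    borrow:
      - from_round: R1
        weight: 0.75
  - id: R3
    n_control: 16
    n_experimental: 63
    allocation: [1, 4]
    borrow:
      - from_round: R1
        weight: 0.75
      - from_round: R2
        weight: 0.75
rule:
  margin: 0.15
  certainty: 0.60
grid:
  rounds: [R3]
  control_rates: [0.40, 0.50, 0.60]
  differences: [-0.10, 0.0, 0.15, 0.25]
  certainties: [0.50, 0.60, 0.70, 0.80]
  weights: [0.5, 0.75]
sim:
  reps: 10000
  seed: 20240003
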