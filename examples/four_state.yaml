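states:
- S1
- S2
- S3
- S4
rates:
- source: S1
  target: S2
  rate: 0.05
- source: S1
  target: S3
  rate: 0.01
- source: S1
  target: S4
  rate: 0.001
- source: S2
  target: S3
  rate: 0.1
- source: S2
  target: S4
  rate: 0.05
- source: S3
  target: S4
  rate: 2.0
initial:
  counts:
  - 10000
  - 0
  - 0
  - 0
grid:
  t0: 0.0
  cycle: 1.0
  n_cycles: 50
engine:
  replicates: 1000
  seed: 1
  t_max: 50.0
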