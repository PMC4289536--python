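# Coin-flip kernel model: two advective kernels chosen i.i.d. with equal
# probability each year (low-flow year with R=1.2, high-flow year with R=1.5).
experiment: stochastic
habitat:
  x0: 0.0
  y0: 20.0
  n: 401
stages:
  - {v: 0.1, D: 1.0, beta: 1.0, R: 1.2}
  - {v: 1.0, D: 1.0, beta: 1.0, R: 1.5}
environment:
  kind: coinflip
  p: 0.5
solver:
  T: 5000
  replicates: 8
seed: 0
output_dir: results
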