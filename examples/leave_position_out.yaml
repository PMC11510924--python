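# Leave-position-out at a 0.5 cm offset; the held-out placement (last entry)
# is surrounded by training placements 0.5 cm away.
scenario: position
seed: 1
solver:
  n_ports: 16
positions:
  - {}
  - {dx: -0.5}
  - {dz: 0.5}
  - {dz: -0.5}
  - {dx: 0.5, dz: 0.5, theta: -3.6}
  - {dx: 0.5, dz: -0.5, theta: 3.6}
  - {dx: 1.0}
  - {dx: 0.5}
test_position: 7
svm:
  C_grid: [6.0e3, 2.0e4, 6.0e4]
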