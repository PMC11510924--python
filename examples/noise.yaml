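# End-to-end noise-study manifest: `mwchamber evaluate examples/noise.yaml --out runs/noise`
scenario: noise
seed: 1
solver:
  n_ports: 16        # 32 reproduces the published feature length 2048
svm:
  C_grid: [6.0e3, 6.0e5, 6.0e6, 6.0e7]
  cv_folds: 5
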