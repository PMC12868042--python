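# Smoke-scale end-to-end pipeline config for `phantomforge run`.
# Completes in a few minutes on one CPU.
phantom:
  shape: [4, 128, 128]
degradation:
  noise_sigma: 40.0
  noise_corr: 1.0
  bias_amplitude: 0.1
gan:
  epochs: 2
  n_res_blocks: 1
  base_filters: 8
  input_size: 64
  lambda_int: 1.0
  lambda_gdl: 1.0
patch_size: 64
stride: 32
per_slice: 2
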