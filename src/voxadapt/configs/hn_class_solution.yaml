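# Head-and-neck-style class-solution constraint set with two prescription
# levels (70 / 46 Gy).  VOI names match the two-targets phantom.
constraints:
  ptv70: {d_max: 70.0, p_max: 6000.0, d_min: 70.0, p_min: 10000.0}
  ptv46: {d_max: 46.0, p_max: 4000.0, d_min: 46.0, p_min: 6000.0}
  body: {d_max: 25.0, p_max: 4000.0}
adaptation:
  alpha: 1.0
  d_T: 35.0
  delta_delta: 12.0
  sigma_p: 3.2
  n_runs: 2
  mode: physical
optimizer:
  max_iter: 500
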