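# 1D penumbra demonstration: unit prescription in a central target
# (p_min = 500) against a weak zero-dose wish in the normal tissue
# (p_max = 1).  Shows the coverage loss induced by naive penalty scaling
# at the target border.
constraints:
  target: {d_min: 1.0, p_min: 500.0}
  body: {d_max: 0.0, p_max: 1.0}
adaptation:
  alpha: 1.0
  d_T: 0.5
  delta_delta: 12.0
  sigma_p: 3.2
  n_runs: 1
  mode: physical
optimizer:
  max_iter: 500
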