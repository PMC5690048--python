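# Prostate-style class-solution constraint set (one set reused across
# cases of the indication instead of per-case tuning).  VOI names match
# the prostate2d phantom.
constraints:
  ctv: {d_max: 78.0, p_max: 2500.0, d_min: 78.0, p_min: 2500.0}
  ptv: {d_max: 70.0, p_max: 1500.0, d_min: 70.0, p_min: 4000.0}
  bladder: {d_max: 15.0, p_max: 300.0}
  rectum: {d_max: 15.0, p_max: 200.0}
  body: {d_max: 25.0, p_max: 8000.0}
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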