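# Dose-modifier truth: the CA-additive curve evaluated at kappa * c.
# kappa > 1 makes the mixture stronger than CA predicts (synergism-like),
# kappa < 1 weaker (antagonism-like).  A harness device for testing the
# classifier, not a toxicological mechanism.
scenario:
  seed: 3
  n_points: 12
  replicates: 3
  interaction_mode: dose_modifier
  kappa: 3.0
  noise:
    sigma_od: 0.02
  components:
    As:
      model: Logit
      alpha: 6.4033
      beta: 2.4878
      alpha_sign: -1
      window: [10000, 10]
    Pb:
      model: Logit
      alpha: 8.5098
      beta: 1.9786
      alpha_sign: -1
  rays:
    fixed:
      - {id: Rf, ratio: [1, 10]}
output_dir: raymix_out/dose_modifier
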