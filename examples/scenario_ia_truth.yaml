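# Bliss/IA-independent mixture truth: component effects combine as the
# probabilistic union at their partial concentrations.
scenario:
  seed: 2
  n_points: 12
  replicates: 3
  interaction_mode: IA_truth
  kappa: 1.0
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
    equray: 5
    fixed:
      - {id: Rf, ratio: [1, 10]}
output_dir: raymix_out/ia_truth
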