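# Two-metal study emulation: Loewe/CA-additive mixture truth.
# Component truths are Logit curves in the mirrored single-compound
# convention (EC50 = 10^(+alpha/beta), concentrations in ug/L).
# Design windows default to the concentrations at 98% / 1% inhibition
# unless given explicitly as [c_high, c_low].
scenario:
  seed: 1
  n_points: 12
  replicates: 3
  interaction_mode: CA_truth
  kappa: 1.0
  noise:
    sigma_od: 0.02
    control_od: 0.70
    background_od: 0.0
  components:
    As:
      model: Logit
      alpha: 6.4033
      beta: 2.4878
      alpha_sign: -1
      conc_scale: ugL
      window: [10000, 10]
    Pb:
      model: Logit
      alpha: 8.5098
      beta: 1.9786
      alpha_sign: -1
      conc_scale: ugL
  rays:
    equray: 5
    fixed:
      - {id: Rf, ratio: [1, 10]}
output_dir: raymix_out/ca_truth
confidence_level: 0.95
noec_method: dunnett
orientation: effect_axis
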