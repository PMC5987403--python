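# Demo pipeline configuration: simulate a two-trait cohort and run every
# analysis stage.  Usage:
#   pedeval pipeline --config examples/demo_config.yaml --out reports/
seed: 1
simulate:
  n_sires: 15
  n_dams_per_sire: 2
  n_offspring_per_family: 25
  trait_names: [W3, W4]
  trait_means: {W3: 492.8, W4: 1073.0}
  phenotypic_sd: {W3: 150.9, W4: 131.3}
  genetic_corr: [[1.0, 0.6], [0.6, 1.0]]
  residual_corr: [[1.0, 0.3], [0.3, 1.0]]
  environment_effects:
    cage: 0.0
    tank: {W3: -150.0, W4: -300.0}
analyses:
  summary: true
  lrt: true
  univariate:
    traits: [W3, W4]
  survival:
    links: [logit, probit]
  bivariate:
    pairs: [[W3, W4]]
  gxe:
    traits: [W4]
  ebv:
    trait: W4
  matings:
    n_pairs: 10
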