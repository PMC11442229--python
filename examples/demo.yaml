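# Demo pipeline configuration: a small synthetic four-way cross with two
# traits, one sharing a major QTL on linkage group 2.
seed: 7
outdir: scratch/demo_out
population: SIM01
study: this_study
simulate:
  n_lg: 3
  markers_per_lg: 11
  length_cm: 100
  n_progeny: 120
  years: [2011, 2012, 2013]
  uprights_per_genotype: 10
  n_field_cols: 12
  traits:
    TY:
      mu: 20.0
      qtl:
        - {linkage_group: 2, position: 50, maternal: 1.2, paternal: 0.8}
      polygenic_variance: 0.5
      gxy_variance: 0.2
      residual_variance: 1.0
      spatial_amplitude: 0.3
      row_variance: 0.1
    UBM:
      mu: 2.0
      qtl:
        - {linkage_group: 2, position: 52, maternal: 0.9}
        - {linkage_group: 3, position: 20, paternal: 0.7}
      polygenic_variance: 0.3
      gxy_variance: 0.1
      residual_variance: 0.8
      spatial_amplitude: 0.2
  # categorical berry-shape scores fused into chimera descriptors (UK* traits)
  shape:
    uprights: 10
    concentration: 2.0
    size: 128
    area: 3000
blup:
  spline_knots: [4, 4]
scan:
  step: 2.0
  n_perm: 300
  percentile: 80
metaqtl:
  min_models: 3
  min_r2: 0.10
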