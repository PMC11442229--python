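# Trait-group definitions for multi-trait / cross-study meta-QTL assembly.
# Each group lists synonym traits analyzed together; filters are combined
# with a logical AND. Statistics: mean_marker_r2, n_models, n_traits,
# n_populations, n_studies, n_methods.
- group_id: berry_mass
  traits: [MFM, UMFM, UBM, UTBM, UBW]
  filters:
    - {statistic: mean_marker_r2, comparator: ">=", value: 0.10}
    - {statistic: n_models, comparator: ">=", value: 4}
- group_id: yield
  traits: [TY, SFY, PAC]
  filters:
    - {statistic: mean_marker_r2, comparator: ">=", value: 0.10}
    - {statistic: n_models, comparator: ">=", value: 4}
- group_id: berry_shape
  traits: [UBL, ULvW, UKLvW, UKEC]
  filters:
    - {statistic: mean_marker_r2, comparator: ">=", value: 0.10}
    - {statistic: n_models, comparator: ">=", value: 4}
# cross-population set: requires support from at least two populations
- group_id: berry_mass_xpop
  traits: [MFM, UMFM, UBM, UBW]
  filters:
    - {statistic: mean_marker_r2, comparator: ">=", value: 0.10}
    - {statistic: n_models, comparator: ">=", value: 4}
    - {statistic: n_populations, comparator: ">=", value: 2}
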