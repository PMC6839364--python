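# ICRP publication 103 tissue weighting factors.
#
# `full` is the complete scheme (weights sum to 1.0 with the 13-organ
# remainder).  `study_subset` is the scheme applied to CBCT dose tables in
# which only 15 thoraco-abdominal organs were contoured: 8 organs carry
# their explicit weight and 7 measured remainder organs share the 0.12
# remainder weight, still divided by the full remainder count of 13
# (unmeasured remainder organs count as zero dose).
radiation_weight_photon: 1.0
full:
  explicit_weights:
    gonads: 0.08
    bone_marrow: 0.12
    colon: 0.12
    lung: 0.12
    stomach: 0.12
    breast: 0.12
    bladder: 0.04
    esophagus: 0.04
    liver: 0.04
    thyroid: 0.04
    bone_surface: 0.01
    brain: 0.01
    salivary_glands: 0.01
    skin: 0.01
  remainder_weight: 0.12
  remainder_divisor: 13
  remainder_organs:
    - adrenal_glands
    - extrathoracic_region
    - gallbladder
    - heart
    - kidney
    - lymphatic_nodes
    - muscle
    - oral_mucosa
    - pancreas
    - prostate_uterus
    - small_intestine
    - spleen
    - thymus
study_subset:
  explicit_weights:
    lung: 0.12
    stomach: 0.12
    bone_marrow: 0.12
    esophagus: 0.04
    liver: 0.04
    thyroid: 0.04
    bone_surface: 0.01
    skin: 0.01
  remainder_weight: 0.12
  remainder_divisor: 13
  remainder_organs:
    - adrenal_glands
    - gallbladder
    - heart
    - intestine
    - kidney
    - pancreas
    - spleen
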