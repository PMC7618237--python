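# Default 20-group NCD cause map: 16 named leading causes or
# aetiologically related groups plus 4 residual groups.  The member
# codes listed here are the group identifiers themselves (an identity
# map), suitable for inputs whose cause column already carries group
# labels, such as the surfaces written by the synthetic generator.
# For a real detailed-cause input, replace `codes` with the detailed
# cause codes of the source's classification; the 16-named + 4-residual
# structure is enforced on load.
#
# `sdg34: true` tags groups in the SDG target 3.4 cause superset
# (cancers, cardiovascular diseases, chronic respiratory diseases,
# diabetes).
groups:
  ischaemic_heart_disease: {kind: named, sdg34: true, codes: [ischaemic_heart_disease]}
  stroke: {kind: named, sdg34: true, codes: [stroke]}
  lung_cancer: {kind: named, sdg34: true, codes: [lung_cancer]}
  stomach_cancer: {kind: named, sdg34: true, codes: [stomach_cancer]}
  colorectal_cancer: {kind: named, sdg34: true, codes: [colorectal_cancer]}
  breast_cancer: {kind: named, sdg34: true, codes: [breast_cancer]}
  cervical_cancer: {kind: named, sdg34: true, codes: [cervical_cancer]}
  prostate_cancer: {kind: named, sdg34: true, codes: [prostate_cancer]}
  pancreatic_cancer: {kind: named, sdg34: true, codes: [pancreatic_cancer]}
  liver_cancer: {kind: named, sdg34: true, codes: [liver_cancer]}
  copd: {kind: named, sdg34: true, codes: [copd]}
  diabetes_ckd: {kind: named, sdg34: true, codes: [diabetes_ckd]}
  kidney_diseases: {kind: named, sdg34: false, codes: [kidney_diseases]}
  liver_cirrhosis: {kind: named, sdg34: false, codes: [liver_cirrhosis]}
  alzheimer_dementias: {kind: named, sdg34: false, codes: [alzheimer_dementias]}
  alcohol_use_disorders: {kind: named, sdg34: false, codes: [alcohol_use_disorders]}
  other_circulatory: {kind: residual, sdg34: true, codes: [other_circulatory]}
  other_malignant_neoplasms: {kind: residual, sdg34: true, codes: [other_malignant_neoplasms]}
  other_neuropsychiatric: {kind: residual, sdg34: false, codes: [other_neuropsychiatric]}
  other_ncds: {kind: residual, sdg34: false, codes: [other_ncds]}
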