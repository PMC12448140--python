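{
  "description": "Default controlled vocabulary for a longitudinal heterotaxy cohort with right isomerism. SYNTHETIC/illustrative: variable names follow the anatomy annotated in such cohorts (ventricle laterality, great-artery malposition, apex position, ventriculo-arterial connection, hypoplasias, atrial situs, arch side, venous returns, bronchial isomerism); the exact levels of any real supplementary table should be supplied as a user schema.",
  "variables": [
    {"name": "looping_class", "role": "E9.5", "levels": ["1", "2", "3", "4"], "missing_codes": ["unknown"], "analysis_sets": []},
    {"name": "ventricle_laterality", "role": "E18.5", "levels": ["D", "L"], "missing_codes": ["unknown"], "analysis_sets": ["mca", "classify"]},
    {"name": "ivs_orientation", "role": "E18.5", "levels": ["normal", "superoinferior", "strictly_left_right"], "missing_codes": ["unknown"], "analysis_sets": ["mca", "classify"]},
    {"name": "ga_malposition", "role": "E18.5", "levels": ["D", "L", "A"], "missing_codes": ["unknown"], "analysis_sets": ["mca", "classify"]},
    {"name": "apex_position", "role": "E18.5", "levels": ["levocardia", "mesocardia", "dextrocardia"], "missing_codes": ["unknown"], "analysis_sets": ["mca", "classify"]},
    {"name": "va_connection", "role": "E18.5", "levels": ["DORV", "TGA", "other"], "missing_codes": ["unknown"], "analysis_sets": ["mca", "classify"]},
    {"name": "ventricle_hypoplasia", "role": "E18.5", "levels": ["balanced", "hypoplastic_RV", "hypoplastic_LV"], "missing_codes": ["unknown"], "analysis_sets": ["mca", "classify"]},
    {"name": "trunk_hypoplasia", "role": "E18.5", "levels": ["balanced", "hypoplastic_aorta", "hypoplastic_PT"], "missing_codes": ["unknown"], "analysis_sets": ["mca", "classify"]},
    {"name": "atrial_situs", "role": "E18.5", "levels": ["solitus", "inversus", "right_isomerism"], "missing_codes": ["unknown", "ambiguous"], "analysis_sets": ["mca", "classify"]},
    {"name": "aortic_arch_side", "role": "E18.5", "levels": ["left", "right"], "missing_codes": ["unknown"], "analysis_sets": ["mca", "classify"]},
    {"name": "systemic_venous_return", "role": "E18.5", "levels": ["normal", "abnormal"], "missing_codes": ["unknown"], "analysis_sets": ["mca", "classify"]},
    {"name": "pulmonary_venous_return", "role": "E18.5", "levels": ["normal", "abnormal"], "missing_codes": ["unknown"], "analysis_sets": ["mca", "classify"]},
    {"name": "bronchial_isomerism", "role": "E18.5", "levels": ["right_isomerism", "normal"], "missing_codes": ["unknown"], "analysis_sets": ["classify"]},
    {"name": "avsd", "role": "E18.5", "levels": ["complete", "partial", "none"], "missing_codes": ["unknown"], "analysis_sets": ["classify"]},
    {"name": "vsd", "role": "E18.5", "levels": ["yes", "no"], "missing_codes": ["unknown"], "analysis_sets": ["classify"]}
  ],
  "analysis_sets": {
    "mca": {
      "variables": ["ventricle_laterality", "ivs_orientation", "ga_malposition", "apex_position", "va_connection", "ventricle_hypoplasia", "trunk_hypoplasia", "atrial_situs", "aortic_arch_side", "systemic_venous_return", "pulmonary_venous_return"],
      "required_known": ["looping_class", "ventricle_laterality", "ivs_orientation", "ga_malposition", "apex_position", "va_connection", "ventricle_hypoplasia", "trunk_hypoplasia", "atrial_situs", "aortic_arch_side", "systemic_venous_return", "pulmonary_venous_return"]
    },
    "classify": {
      "variables": ["ventricle_laterality", "ivs_orientation", "ga_malposition", "apex_position", "va_connection", "ventricle_hypoplasia", "trunk_hypoplasia", "atrial_situs", "aortic_arch_side", "systemic_venous_return", "pulmonary_venous_return", "bronchial_isomerism", "avsd", "vsd"],
      "required_known": ["looping_class", "ventricle_laterality"]
    }
  }
}
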