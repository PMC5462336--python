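{
 "comment": "Quantitative image biomarkers and the graded regions they require. Whole-lung measures require a good lung segmentation; other biomarkers need acceptable or better.",
 "biomarkers": [
  {"name": "airway_lumen_diameter", "requires": {"airway": "acceptable"}},
  {"name": "airway_wall_thickness", "requires": {"airway": "acceptable"}},
  {"name": "pulmonary_nodule_detection", "requires": {"lung": "good"}},
  {"name": "pulmonary_nodule_measurement", "requires": {"lung": "good"}},
  {"name": "pulmonary_nodule_pair_measurement", "requires": {"lung": "good"}},
  {"name": "pulmonary_nodule_characterization", "requires": {"lung": "good"}},
  {"name": "emphysema_index", "requires": {"lung": "good"}},
  {"name": "coronary_artery_calcium", "requires": {"cardiac region": "acceptable"}},
  {"name": "aortic_calcium", "requires": {"cardiac region": "acceptable"}},
  {"name": "pulmonary_trunk_diameter", "requires": {"cardiac region": "acceptable"}},
  {"name": "cardiac_visceral_fat", "requires": {"cardiac region": "acceptable"}},
  {"name": "breast_density", "requires": {"breast": "acceptable"}}
 ]
}
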