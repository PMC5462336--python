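{
 "comment": "Chest-analysis module graph. 'depends' maps prerequisite module -> minimum grade of its produced regions. Only dependencies stated by the pipeline design are recorded; modules with no documented prerequisites beyond the image-quality profile depend on image_quality alone.",
 "modules": [
  {"name": "image_quality", "produces": [], "depends": {}},
  {"name": "airway", "produces": ["airway"], "depends": {"image_quality": "acceptable"}},
  {"name": "lung", "produces": ["lung"], "depends": {"airway": "acceptable"}},
  {"name": "nodules", "produces": [], "depends": {"lung": "acceptable"}},
  {"name": "skin", "produces": ["skin"], "depends": {"image_quality": "acceptable"}},
  {"name": "fat", "produces": [], "depends": {"skin": "acceptable"}},
  {"name": "bone", "produces": [], "depends": {"image_quality": "acceptable"}},
  {"name": "ribs", "produces": ["rib"], "depends": {"bone": "acceptable"}},
  {"name": "vertebra", "produces": ["vertebra"], "depends": {"bone": "acceptable"}},
  {"name": "sternum", "produces": [], "depends": {"bone": "acceptable"}},
  {"name": "aorta", "produces": ["cardiac region"], "depends": {"lung": "acceptable", "bone": "acceptable"}},
  {"name": "heart", "produces": ["cardiac region"], "depends": {"aorta": "acceptable", "lung": "acceptable"}},
  {"name": "pulmonary_artery", "produces": ["cardiac region"], "depends": {"heart": "acceptable"}},
  {"name": "breast", "produces": ["breast"], "depends": {"sternum": "acceptable", "skin": "acceptable"}}
 ]
}
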