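# Approximate ICD-10 prefix sets per ophthalmic diagnosis cohort. These are
# plausible stand-in code groups for cohort construction and testing, not a
# certified billing mapping: replace with your registry's curated code sets
# before clinical use. A registry code matches a cohort when it starts with
# any listed prefix.
diabetic_retinopathy_with_dme:
  - E08.311
  - E09.311
  - E10.311
  - E11.311
  - E13.311
diabetic_retinopathy_without_dme:
  - E08.319
  - E09.319
  - E10.319
  - E11.319
  - E13.319
exudative_amd:
  - H35.32
nonexudative_amd:
  - H35.31
geographic_atrophy:
  - H35.3113
  - H35.3123
glaucoma:
  - H40
retinal_vascular_occlusion:
  - H34
choroidal_disorders:
  - H31
hereditary_retinal_dystrophy:
  - H35.5
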