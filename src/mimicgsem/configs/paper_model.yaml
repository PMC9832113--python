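latents:
- malnutrition
- morbidity
indicators:
- name: stunting
  latent: malnutrition
  link: logit
  fixed_loading: 1.0
  direct_covariates:
  - child_sex
  - child_age_group
- name: wasting
  latent: malnutrition
  link: logit
  fixed_loading: null
  direct_covariates:
  - child_sex
  - child_age_group
- name: underweight
  latent: malnutrition
  link: logit
  fixed_loading: null
  direct_covariates:
  - child_sex
  - child_age_group
- name: diarrhea
  latent: morbidity
  link: logit
  fixed_loading: 1.0
  direct_covariates:
  - child_sex
  - child_age_group
- name: cough
  latent: morbidity
  link: logit
  fixed_loading: null
  direct_covariates:
  - child_sex
  - child_age_group
- name: fever
  latent: morbidity
  link: logit
  fixed_loading: null
  direct_covariates:
  - child_sex
  - child_age_group
covariates:
- name: mother_bmi
  levels:
  - <18.5
  - '>=18.5'
  reference: <18.5
- name: birth_order
  levels:
  - 1st
  - 2nd-3rd
  - 4th+
  reference: 1st
- name: birth_interval
  levels:
  - <24
  - 24-47
  - 48+
  reference: <24
- name: wealth_index
  levels:
  - poor
  - middle
  - rich
  reference: poor
- name: mother_education
  levels:
  - none
  - primary
  - secondary+
  reference: none
- name: husband_education
  levels:
  - none
  - primary
  - secondary
  - higher
  reference: none
- name: water_source
  levels:
  - piped
  - public_tap
  - protected_spring
  - other
  reference: piped
- name: toilet_facility
  levels:
  - none
  - latrine
  - flush
  reference: none
- name: breastfeeding
  levels:
  - 'no'
  - 'yes'
  reference: 'no'
- name: anemia
  levels:
  - anemic
  - not_anemic
  reference: anemic
- name: mother_work
  levels:
  - 'no'
  - 'yes'
  reference: 'no'
- name: place_of_delivery
  levels:
  - home
  - health_center
  reference: home
- name: child_sex
  levels:
  - male
  - female
  reference: male
- name: child_age_group
  levels:
  - 0-11
  - 12-23
  - 24-59
  reference: 0-11
latent_paths:
- - malnutrition
  - morbidity
covariate_to_latent_paths:
- - mother_bmi
  - malnutrition
- - birth_interval
  - malnutrition
- - wealth_index
  - malnutrition
- - mother_education
  - malnutrition
- - breastfeeding
  - malnutrition
- - anemia
  - malnutrition
- - mother_work
  - malnutrition
- - place_of_delivery
  - malnutrition
- - mother_bmi
  - morbidity
- - birth_order
  - morbidity
- - birth_interval
  - morbidity
- - water_source
  - morbidity
- - toilet_facility
  - morbidity
- - breastfeeding
  - morbidity
- - anemia
  - morbidity
- - mother_work
  - morbidity
- - place_of_delivery
  - morbidity
- - husband_education
  - morbidity
full_covariance: false
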