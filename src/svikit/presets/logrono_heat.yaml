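# Heat-hazard SVI configuration, Logroño style (Spanish census + Copernicus).
# The Health domain is designed with two indicators but the census publishes
# only the disability rate: the missing required poor-health indicator leaves
# Health depleted, which is what makes this the tier-2 scenario.
name: logrono_heat
hazard: heat
dimensions:
  - {id: sensitivity, label: Sensitivity}
  - {id: adaptive_capacity, label: Adaptive Capacity}
  - {id: enhanced_exposure, label: Enhanced Exposure}
domains:
  - {id: age, label: Age, dimension: sensitivity}
  - {id: health, label: Health, dimension: sensitivity}
  - {id: income, label: Income, dimension: adaptive_capacity}
  - {id: information_access, label: Information Access/Use, dimension: adaptive_capacity}
  - {id: local_knowledge, label: Local Knowledge, dimension: adaptive_capacity}
  - {id: tenure, label: Tenure, dimension: adaptive_capacity}
  - {id: social_network, label: Social Network, dimension: adaptive_capacity}
  - {id: housing_characteristics, label: Housing Characteristics, dimension: enhanced_exposure}
  - {id: physical_environment, label: Physical Environment, dimension: enhanced_exposure}
indicators:
  - id: boys_under_5
    label: Boys under 5 years of age (%)
    domain: age
    direction: vulnerability_increasing
    hazard_tags: [heat]
  - id: girls_under_5
    label: Girls under 5 years of age (%)
    domain: age
    direction: vulnerability_increasing
    hazard_tags: [heat]
  - id: males_over_75
    label: Males over 75 years of age (%)
    domain: age
    direction: vulnerability_increasing
    hazard_tags: [heat]
  - id: females_over_75
    label: Females over 75 years of age (%)
    domain: age
    direction: vulnerability_increasing
    hazard_tags: [heat]
  - id: poor_health
    label: Persons with poor health (%)
    domain: health
    direction: vulnerability_increasing
    hazard_tags: [heat]
    case_study_available: false
  - id: disability_preventing_work
    label: People with a disability preventing work (%)
    domain: health
    direction: vulnerability_increasing
    hazard_tags: [heat]
  - id: one_parent_households
    label: One parent households (%)
    domain: income
    direction: vulnerability_increasing
    sub_abilities: [prepare, respond, recover]
    hazard_tags: [heat]
  - id: dependents_rate
    label: Dependents rate (%)
    domain: income
    direction: vulnerability_increasing
    sub_abilities: [prepare, respond, recover]
    hazard_tags: [heat]
  - id: unemployment
    label: Unemployment (%)
    domain: income
    direction: vulnerability_increasing
    sub_abilities: [prepare, respond, recover]
    hazard_tags: [heat]
  - id: university_students
    label: Population attending university (%)
    domain: income
    direction: vulnerability_increasing
    sub_abilities: [prepare, respond, recover]
    hazard_tags: [heat]
  - id: no_higher_education
    label: Population with no higher education (%)
    domain: information_access
    direction: vulnerability_increasing
    sub_abilities: [prepare, respond, recover]
    hazard_tags: [heat]
  - id: foreign_nationals
    label: Foreign nationals (%)
    domain: local_knowledge
    direction: vulnerability_increasing
    sub_abilities: [prepare, respond]
    hazard_tags: [heat]
  - id: households_renting
    label: Households renting (%)
    domain: tenure
    direction: vulnerability_increasing
    sub_abilities: [prepare]
    hazard_tags: [heat]
  - id: one_person_households
    label: Households with one person (%)
    domain: social_network
    direction: vulnerability_increasing
    sub_abilities: [respond, recover]
    hazard_tags: [heat]
  - id: primary_school_children
    label: Primary school age children (%)
    domain: social_network
    direction: vulnerability_reducing
    sub_abilities: [respond, recover]
    hazard_tags: [heat]
  - id: pre_1970_dwellings
    label: Dwellings built before 1970 (%)
    domain: housing_characteristics
    direction: vulnerability_increasing
    hazard_tags: [heat]
  - id: impervious_surface
    label: Impervious surface share
    domain: physical_environment
    direction: vulnerability_increasing
    hazard_tags: [heat]
  - id: tree_cover
    label: Tree cover share
    domain: physical_environment
    direction: vulnerability_reducing
    hazard_tags: [heat]
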