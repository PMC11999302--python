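# Flood-hazard SVI configuration, Cork City style (Irish census + Copernicus
# land-cover shares).  The complete design: every domain fully populated, at
# least two domains per dimension, hence the tier-1 "ideal scenario".
name: cork_flood
hazard: flood
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
  - {id: mobility, label: Mobility, dimension: adaptive_capacity}
  - {id: physical_access, label: Physical Access, dimension: adaptive_capacity}
  - {id: tenure, label: Tenure, dimension: adaptive_capacity}
  - {id: social_network, label: Social Network, dimension: adaptive_capacity}
  - {id: housing_characteristics, label: Housing Characteristics, dimension: enhanced_exposure}
  - {id: physical_environment, label: Physical Environment, dimension: enhanced_exposure}
indicators:
  - id: children_under_5
    label: Children under 5 years of age (%)
    domain: age
    direction: vulnerability_increasing
    hazard_tags: [flood]
  - id: adults_over_75
    label: Adults over 75 years of age (%)
    domain: age
    direction: vulnerability_increasing
    hazard_tags: [flood]
  - id: poor_health
    label: Persons with poor health (%)
    domain: health
    direction: vulnerability_increasing
    hazard_tags: [flood]
  - id: disability_preventing_work
    label: People with a disability preventing work (%)
    domain: health
    direction: vulnerability_increasing
    hazard_tags: [flood]
  - id: one_parent_households
    label: One parent households (%)
    domain: income
    direction: vulnerability_increasing
    sub_abilities: [prepare, respond, recover]
    hazard_tags: [flood]
  - id: children_per_family
    label: Children per family
    domain: income
    direction: vulnerability_increasing
    sub_abilities: [prepare, respond, recover]
    hazard_tags: [flood]
  - id: low_skilled_employment
    label: Low skilled employment (%)
    domain: income
    direction: vulnerability_increasing
    sub_abilities: [prepare, respond, recover]
    hazard_tags: [flood]
  - id: farming_employment
    label: Population employed in farming (%)
    domain: income
    direction: vulnerability_increasing
    sub_abilities: [prepare, respond, recover]
    hazard_tags: [flood]
  - id: unemployment
    label: Unemployment (%)
    domain: income
    direction: vulnerability_increasing
    sub_abilities: [prepare, respond, recover]
    hazard_tags: [flood]
  - id: no_higher_education
    label: Population with no higher education (%)
    domain: information_access
    direction: vulnerability_increasing
    sub_abilities: [prepare, respond, recover]
    hazard_tags: [flood]
  - id: poor_english
    label: Population who do not speak English well or at all (%)
    domain: information_access
    direction: vulnerability_increasing
    sub_abilities: [prepare, respond, recover]
    hazard_tags: [flood]
  - id: no_internet
    label: Households with no Internet (%)
    domain: information_access
    direction: vulnerability_increasing
    sub_abilities: [prepare, respond, recover]
    hazard_tags: [flood]
  - id: new_residents
    label: New residents (%)
    domain: local_knowledge
    direction: vulnerability_increasing
    sub_abilities: [prepare, respond]
    hazard_tags: [flood]
  - id: foreign_nationals
    label: Foreign nationals (%)
    domain: local_knowledge
    direction: vulnerability_increasing
    sub_abilities: [prepare, respond]
    hazard_tags: [flood]
  - id: no_motor_car
    label: Households with no motor car (%)
    domain: mobility
    direction: vulnerability_increasing
    sub_abilities: [respond, recover]
    hazard_tags: [flood]
  - id: travel_time
    label: Travel time to work/school
    domain: physical_access
    direction: vulnerability_increasing
    sub_abilities: [respond]
    hazard_tags: [flood]
  - id: households_renting
    label: Households renting (%)
    domain: tenure
    direction: vulnerability_increasing
    sub_abilities: [prepare]
    hazard_tags: [flood]
  - id: volunteering
    label: Volunteering (%)
    domain: social_network
    direction: vulnerability_reducing
    sub_abilities: [respond, recover]
    hazard_tags: [flood]
  - id: primary_school_children
    label: Primary school age children (%)
    domain: social_network
    direction: vulnerability_reducing
    sub_abilities: [respond, recover]
    hazard_tags: [flood]
  - id: one_person_households
    label: Households with one person (%)
    domain: social_network
    direction: vulnerability_increasing
    sub_abilities: [respond, recover]
    hazard_tags: [flood]
  - id: no_central_heating
    label: Households with no central heating (%)
    domain: housing_characteristics
    direction: vulnerability_increasing
    sub_abilities: [recover]
    hazard_tags: [flood]
  - id: private_water_supply
    label: Households with private water supplies (%)
    domain: housing_characteristics
    direction: vulnerability_increasing
    sub_abilities: [recover]
    hazard_tags: [flood]
  - id: pre_1945_dwellings
    label: Dwellings built before 1945 (%)
    domain: housing_characteristics
    direction: vulnerability_increasing
    hazard_tags: [flood]
  - id: caravan_mobile_homes
    label: Households that are caravans/mobile homes (%)
    domain: housing_characteristics
    direction: vulnerability_increasing
    hazard_tags: [flood]
  - id: unoccupied_dwellings
    label: Unoccupied dwellings (%)
    domain: housing_characteristics
    direction: vulnerability_increasing
    hazard_tags: [flood]
  - id: impervious_surface
    label: Impervious surface share
    domain: physical_environment
    direction: vulnerability_increasing
    hazard_tags: [flood]
  - id: tree_cover
    label: Tree cover share
    domain: physical_environment
    direction: vulnerability_reducing
    hazard_tags: [flood]
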