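# Nigeria reference scenario, fully itemized from published program
# costing tables. Unit values that print rounded are stored unrounded,
# calibrated so each reproduces its published subtotal (noted inline
# in the generator and in docs/methods.md). Constant 2021 USD.
name: nigeria
approximate: false
horizon: 10
startup_years: 2
population:
  years:
  - 2021
  - 2022
  - 2023
  - 2024
  - 2025
  - 2026
  - 2027
  - 2028
  - 2029
  - 2030
  totals:
  - 211400704.0
  - 216724321.0
  - 222182000.0
  - 227713000.0
  - 233343000.0
  - 239073000.0
  - 244902000.0
  - 250830000.0
  - 256855000.0
  - 262977000.0
  consuming_fraction: 0.983547699065373
strata:
- name: North Central
  population_share: 0.1512
  reach: 1.0
  intake: 4.62
- name: North East
  population_share: 0.1357
  reach: 0.96
  intake: 3.73
- name: North West
  population_share: 0.2529
  reach: 0.98
  intake: 3.91
- name: South East
  population_share: 0.1135
  reach: 0.96
  intake: 3.86
- name: South South
  population_share: 0.149
  reach: 1.0
  intake: 3.71
- name: South West
  population_share: 0.1977
  reach: 0.98
  intake: 2.58
availability_override: 3.6332178864100433
domestic_share: 0.9
industrial_share: 1.0
compliance: 0.75
n_factories: 8
n_ports: 10
production_days: 250
premix:
  nutrients:
  - name: iron
    compound: micronized ferric pyrophosphate
    activity: 0.25
    target_level: 2640.0
    overage_fraction: 0.0
    price: 11.5
  - name: vitamin_a
    compound: retinyl palmitate 250,000 IU/g (dry)
    activity: 0.075
    target_level: 96.0
    overage_fraction: 0.3
    price: 55.0
  - name: zinc
    compound: zinc oxide
    activity: 0.8
    target_level: 1680.0
    overage_fraction: 0.0
    price: 7.0
  - name: vitamin_b12
    compound: vitamin B-12 0.1% WS
    activity: 0.001
    target_level: 0.288
    overage_fraction: 0.3
    price: 45.0
  - name: folic_acid
    compound: folic acid
    activity: 0.9
    target_level: 28.8
    overage_fraction: 0.3
    price: 65.0
  addition_rate: 16250.0
  excipient_price: 1.5
  upcharge_per_kg: 1.0
channels:
  domestic_production:
    duty_fraction: 0.2
    transport_per_kg: 0.2
  imported_product:
    duty_fraction: 0.0
    transport_per_kg: 0.2
firm_mgmt_rate: 0.05
gov_mgmt_rate: 0.05
cost_items:
- label: feeder and installation
  actor: firm
  phase: startup
  category: equipment
  scope: per_factory
  quantity: 1
  unit_price: 5000.0
  markups: &id001
  - - import duty
    - 0.1
  - - shipping
    - 0.1
  - - vat
    - 0.08
  year_schedule: &id002
  - 1.0
  - 0
  - 0
  - 0
  - 0
  - 0
  - 0
  - 0
  - 0
  - 0
- label: portable fluorometer
  actor: firm
  phase: startup
  category: equipment
  scope: per_factory
  quantity: 1
  unit_price: 8690.0
  markups: *id001
  year_schedule: *id002
- label: portable photometer
  actor: firm
  phase: startup
  category: equipment
  scope: per_factory
  quantity: 1
  unit_price: 3373.0
  markups: *id001
  year_schedule: *id002
- label: manual centrifuge
  actor: firm
  phase: startup
  category: equipment
  scope: per_factory
  quantity: 1
  unit_price: 476.0
  markups: *id001
  year_schedule: *id002
- label: label and printing plate redesign
  actor: firm
  phase: startup
  category: labeling
  scope: per_factory
  quantity: 1
  unit_price: 327.125
  year_schedule: *id002
- label: fortification/QA training sessions
  actor: firm
  phase: startup
  category: training
  scope: per_factory
  quantity: 3
  unit_price: 249.125
  year_schedule:
  - 1.0
  - 1.0
  - 0
  - 0
  - 0
  - 0
  - 0
  - 0
  - 0
  - 0
- label: program planning, design and data collection
  actor: government
  phase: startup
  category: planning
  scope: national
  quantity: 1
  unit_price: 330000.0
  year_schedule: *id002
- label: laboratory equipment and installation
  actor: government
  phase: startup
  category: equipment
  scope: national
  quantity: 1
  unit_price: 243245.0
  year_schedule: *id002
- label: social marketing (start-up)
  actor: government
  phase: startup
  category: social_marketing
  scope: national
  quantity: 1
  unit_price: 85987.0
  year_schedule: &id003
  - 0.5
  - 0.5
  - 0
  - 0
  - 0
  - 0
  - 0
  - 0
  - 0
  - 0
- label: training of monitoring personnel
  actor: government
  phase: startup
  category: training
  scope: national
  quantity: 1
  unit_price: 57324.0
  year_schedule: *id003
- label: fortification labor (1 FTE)
  actor: firm
  phase: operational
  category: fortification
  scope: per_factory
  quantity: 1
  unit_price: 10093.75
  year_schedule: &id004
  - 0
  - 0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
- label: fortification equipment maintenance
  actor: firm
  phase: operational
  category: fortification
  scope: per_factory
  quantity: 0.07
  unit_price: 12539.0
  year_schedule: *id004
- label: in-house fluorometer reagents
  actor: firm
  phase: operational
  category: qa_qc
  scope: per_factory
  quantity: 750
  unit_price: 8.0
  year_schedule: *id004
- label: QA/QC personnel (1 FTE)
  actor: firm
  phase: operational
  category: qa_qc
  scope: per_factory
  quantity: 1
  unit_price: 12617.25
  year_schedule: *id004
- label: external lab quantitative testing
  actor: firm
  phase: operational
  category: external_qa_qc
  scope: per_factory
  quantity: 12
  unit_price: 62.28125
  year_schedule: *id004
- label: retraining sessions
  actor: firm
  phase: operational
  category: training
  scope: per_factory
  quantity: 1
  unit_price: 249.125
  year_schedule: *id004
- label: factory inspections
  actor: government
  phase: operational
  category: factory_monitoring
  scope: national
  quantity: 96
  unit_price: 161.9375
  year_schedule: &id005
  - 0
  - 0
  - 1.0
  - 1.0
  - 1.0
  - 0.5
  - 0.5
  - 0.5
  - 0.5
  - 0.5
  management_base: true
- label: factory sample reagents (vitamin A)
  actor: government
  phase: operational
  category: factory_monitoring
  scope: national
  quantity: 480
  unit_price: 8.0
  year_schedule: *id005
  management_base: true
- label: import monitoring personnel (0.5 FTE/port)
  actor: government
  phase: operational
  category: import_monitoring
  scope: per_port
  quantity: 0.5
  unit_price: 12617.25
  year_schedule: *id004
  management_base: true
- label: import consignment reagents
  actor: government
  phase: operational
  category: import_monitoring
  scope: per_port
  quantity: 50
  unit_price: 7.63
  year_schedule: *id004
  management_base: true
- label: commercial monitoring personnel (1 FTE)
  actor: government
  phase: operational
  category: commercial_monitoring
  scope: national
  quantity: 1
  unit_price: 12617.25
  year_schedule: *id004
  management_base: true
- label: commercial outlet reagents
  actor: government
  phase: operational
  category: commercial_monitoring
  scope: national
  quantity: 600
  unit_price: 7.63
  year_schedule: *id004
  management_base: true
- label: household monitoring survey
  actor: government
  phase: operational
  category: household_monitoring
  scope: national
  quantity: 1
  unit_price: 30000.0
  year_schedule:
  - 0
  - 0
  - 0
  - 1.0
  - 0
  - 0
  - 0
  - 0
  - 0
  - 0
  management_base: true
- label: national nutrition surveillance (inactive)
  actor: government
  phase: operational
  category: surveillance
  scope: national
  quantity: 1
  unit_price: 550000.0
  year_schedule:
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- label: social marketing
  actor: government
  phase: operational
  category: social_marketing
  scope: national
  quantity: 1
  unit_price: 10000.0
  year_schedule: *id004
- label: regulator retraining sessions
  actor: government
  phase: operational
  category: training
  scope: national
  quantity: 8
  unit_price: 4982.625
  year_schedule: *id004
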