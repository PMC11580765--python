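# Burkina Faso reference scenario (approximate). Cost schedules are
# aggregate category totals calibrated to published phase totals;
# itemized schedules for this country are not published. 2021 USD.
name: burkina_faso
approximate: true
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
  - 21497097.0
  - 22099015.72
  - 22717788.16
  - 23353886.22
  - 24007795.04
  - 24680013.3
  - 25371053.67
  - 26081443.17
  - 26811723.58
  - 27562451.84
  consuming_fraction: 0.8202848040365637
strata:
- name: Boucle de Mouhoun
  population_share: 0.0969928217281069
  reach: 0.81
  intake: 1.8
- name: Cascades
  population_share: 0.04094273942861864
  reach: 0.7
  intake: 1.84
- name: Centre
  population_share: 0.14320543574815872
  reach: 0.74
  intake: 1.38
- name: Centre-Est
  population_share: 0.07925596089816038
  reach: 0.81
  intake: 1.88
- name: Centre-Nord
  population_share: 0.08308075658219138
  reach: 0.89
  intake: 1.1
- name: Centre-Ouest
  population_share: 0.08076160612577625
  reach: 0.89
  intake: 0.9
- name: Centre-Sud
  population_share: 0.04275563545885454
  reach: 0.85
  intake: 1.81
- name: Est
  population_share: 0.08794964678019766
  reach: 0.8
  intake: 1.34
- name: Hauts Bassins
  population_share: 0.10680972909085022
  reach: 0.8
  intake: 1.82
- name: Nord
  population_share: 0.08015110506088823
  reach: 0.8
  intake: 0.71
- name: Plateau Central
  population_share: 0.04658750186536823
  reach: 0.87
  intake: 1.27
- name: Sahel
  population_share: 0.06887637288310942
  reach: 0.95
  intake: 1.87
- name: Sud-Ouest
  population_share: 0.04263068834971942
  reach: 0.84
  intake: 0.86
availability_override: 1.1735357104263893
domestic_share: 0.1
industrial_share: 1.0
compliance: 0.75
n_factories: 1
n_ports: 4
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
    duty_fraction: 0.2
    transport_per_kg: 0.2
firm_mgmt_rate: 0.0
gov_mgmt_rate: 0.0
cost_items:
- label: government start-up activities (aggregate)
  actor: government
  phase: startup
  category: startup_aggregate
  scope: national
  quantity: 1
  unit_price: 582835.5
  year_schedule: &id001
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
- label: industry start-up activities (aggregate)
  actor: firm
  phase: startup
  category: startup_aggregate
  scope: national
  quantity: 1
  unit_price: 64759.5
  year_schedule: *id001
- label: government operational activities (aggregate)
  actor: government
  phase: operational
  category: operational_aggregate
  scope: national
  quantity: 1
  unit_price: 53979.31
  year_schedule: &id002
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
- label: industry operational activities (aggregate)
  actor: firm
  phase: operational
  category: operational_aggregate
  scope: national
  quantity: 1
  unit_price: 53979.32
  year_schedule: *id002
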