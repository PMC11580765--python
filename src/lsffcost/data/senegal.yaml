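# Senegal reference scenario (approximate). Cost schedules are
# aggregate category totals calibrated to published phase totals;
# itemized schedules for this country are not published. 2021 USD.
name: senegal
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
  - 17196308.0
  - 17643412.01
  - 18102140.72
  - 18572796.38
  - 19055689.08
  - 19551137.0
  - 20059466.56
  - 20581012.69
  - 21116119.02
  - 21665138.12
  consuming_fraction: 0.8952684494834589
strata:
- name: Dakar
  population_share: 0.23223496578451608
  reach: 0.84
  intake: 2.45
- name: Ziguinchor
  population_share: 0.04065163289701487
  reach: 0.94
  intake: 2.32
- name: Diourbel
  population_share: 0.11085100359914465
  reach: 0.91
  intake: 2.79
- name: Saint-Louis
  population_share: 0.06728560572420546
  reach: 0.94
  intake: 2.29
- name: Tambacounda
  population_share: 0.050434837524426755
  reach: 0.9
  intake: 2.2
- name: Kaolack
  population_share: 0.0711300355867085
  reach: 0.94
  intake: 1.62
- name: Thies
  population_share: 0.13242295962598483
  reach: 0.88
  intake: 2.46
- name: Louga
  population_share: 0.06471325123974285
  reach: 0.92
  intake: 2.34
- name: Fatick
  population_share: 0.052883793428217266
  reach: 0.94
  intake: 2.21
- name: Kolda
  population_share: 0.04903907280562781
  reach: 0.96
  intake: 1.75
- name: Matam
  population_share: 0.04164265957553214
  reach: 0.93
  intake: 1.87
- name: Kaffrine
  population_share: 0.041972323361502945
  reach: 0.89
  intake: 1.49
- name: Kedougou
  population_share: 0.011204381777762994
  reach: 0.92
  intake: 5.86
- name: Sedhiou
  population_share: 0.03353347706961285
  reach: 0.94
  intake: 1.6
availability_override: 2.002873233021879
domestic_share: 0.1
industrial_share: 1.0
compliance: 0.75
n_factories: 1
n_ports: 3
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
  unit_price: 571957.76
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
  unit_price: 77994.24
  year_schedule: *id001
- label: government operational activities (aggregate)
  actor: government
  phase: operational
  category: operational_aggregate
  scope: national
  quantity: 1
  unit_price: 58303.33
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
  unit_price: 68443.04
  year_schedule: *id002
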