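# Zambia national viral-load scale-up inputs.
#
# Assay performance is specimen x platform at the 1000 copies/mL failure
# threshold (point estimate with low/high bounds used in sensitivity
# analysis). Unit costs are USD per test on the Roche platform, split into
# collection consumables, collection staff/equipment/overhead, and
# centralised laboratory analysis; result-reporting costs are excluded.
# The `golden` block carries the published scenario-level reference
# figures used by the pinned-count run mode.

seed: 2019

assays:
  - {specimen: plasma, platform: capctm, sensitivity: 0.983, specificity: 0.994,
     sens_low: 0.967, sens_high: 0.993, spec_low: 0.983, spec_high: 0.999}
  - {specimen: psc, platform: capctm, sensitivity: 0.91, specificity: 0.99,
     sens_low: 0.84, sens_high: 0.96, spec_low: 0.98, spec_high: 1.0}
  - {specimen: psc, platform: cobas8800, sensitivity: 0.970, specificity: 0.972,
     sens_low: 0.924, sens_high: 0.992, spec_low: 0.949, spec_high: 0.986}
  - {specimen: dbs, platform: capctm, sensitivity: 0.948, specificity: 0.939,
     sens_low: 0.846, sens_high: 0.984, spec_low: 0.720, spec_high: 0.989}

unit_costs:
  - {specimen: plasma, consumables: 0.31, collection_overhead: 0.87, lab_analysis: 17.22}
  - {specimen: dbs, consumables: 0.92, collection_overhead: 0.47, lab_analysis: 17.54}
  - {specimen: psc, consumables: 5.00, collection_overhead: 0.47, lab_analysis: 17.54}

multipliers:
  high_volume: 0.80
  low_volume_plasma: 0.40
  low_volume_dried: 0.80
  unreachable_dried: 0.80

epi:
  # failure prevalence is calibrated from the plasma-only testing cascade:
  # total plasma tests (initial + confirmatory repeats) over patients accessing
  failure_prevalence: null
  correctness_model: product
  calibration:
    observed_tests: 930982
    observed_patients: 814066
    specimen: plasma
    platform: capctm

visit_transport:
  visit_cost: 3.65
  transport_cost_by_scenario:
    plasma_only: 3264509
    dried_partial: 3637168
    dried_full: 2390317

scenarios:
  - name: plasma_only
    specimen_high: plasma
    specimen_low: plasma
    include_unreachable: false
    platform_mix: {capctm: 1.0}
    transport_key: plasma_only
  - name: plasma_dbs
    specimen_high: plasma
    specimen_low: dbs
    include_unreachable: true
    platform_mix: {capctm: 1.0}
    transport_key: dried_partial
  - name: plasma_psc
    specimen_high: plasma
    specimen_low: psc
    include_unreachable: true
    platform_mix: {capctm: 0.42, cobas8800: 0.58}
    transport_key: dried_partial
  - name: dbs_only
    specimen_high: dbs
    specimen_low: dbs
    include_unreachable: true
    platform_mix: {capctm: 1.0}
    transport_key: dried_full
  - name: psc_only
    specimen_high: psc
    specimen_low: psc
    include_unreachable: true
    platform_mix: {capctm: 0.61, cobas8800: 0.39}
    transport_key: dried_full

golden:
  plasma_only:
    access: 814066
    facilities_reached: 800
    correct: 795342
    dried_tests: 0
    plasma_tests: 930982
    visit_count: 931011
    dried_cost: 0.0
    plasma_cost: 17130067.0
    visit_cost: 3398191.0
    transport_cost: 3264509.0
    system_cost: 23792767.0
  plasma_dbs:
    access: 965587
    facilities_reached: 1041
    correct: 920243
    dried_tests: 306860
    plasma_tests: 810283
    visit_count: 1117143
    dried_cost: 5808856.0
    plasma_cost: 14909215.0
    visit_cost: 4081157.0
    transport_cost: 3637168.0
    system_cost: 28436396.0
  plasma_psc:
    access: 965587
    facilities_reached: 1041
    correct: 929857
    dried_tests: 296308
    plasma_tests: 810283
    visit_count: 1106591
    dried_cost: 6818046.0
    plasma_cost: 14909215.0
    visit_cost: 4039542.0
    transport_cost: 3637168.0
    system_cost: 29403970.0
  dbs_only:
    access: 965587
    facilities_reached: 1041
    correct: 856476
    dried_tests: 1152640
    plasma_tests: 0
    visit_count: 1152640
    dried_cost: 21819481.0
    plasma_cost: 0.0
    visit_cost: 4220251.0
    transport_cost: 2390317.0
    system_cost: 28430050.0
  psc_only:
    access: 965587
    facilities_reached: 1041
    correct: 884844
    dried_tests: 1108200
    plasma_tests: 0
    visit_count: 1108200
    dried_cost: 25499686.0
    plasma_cost: 0.0
    visit_cost: 4045952.0
    transport_cost: 2390317.0
    system_cost: 31935954.0
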