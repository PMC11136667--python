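name: product_itaconate
metabolites:
- id: itacon_c
  name: Itaconate
  compartment: c
  formula: C5H4O4
  charge: -2
- id: itacon_e
  name: Itaconate
  compartment: e
  formula: C5H4O4
  charge: -2
add:
- id: CADA
  name: cis-aconitate decarboxylase
  metabolites:
    acon_C_c: -1
    h_c: -1
    itacon_c: 1
    co2_c: 1
  lower_bound: 0
  upper_bound: 1000.0
- id: ITACONt
  name: itaconate export
  metabolites:
    itacon_c: -1
    itacon_e: 1
  lower_bound: 0
  upper_bound: 1000.0
- id: EX_itacon_e
  name: itaconate exchange
  metabolites:
    itacon_e: -1
  lower_bound: 0
  upper_bound: 1000.0
remove: []
bound_changes: {}
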