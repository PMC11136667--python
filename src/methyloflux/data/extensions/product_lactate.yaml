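name: product_lactate
metabolites:
- id: lac__L_c
  name: L-lactate
  compartment: c
  formula: C3H5O3
  charge: -1
- id: lac__L_e
  name: L-lactate
  compartment: e
  formula: C3H5O3
  charge: -1
add:
- id: LDH_L
  name: L-lactate dehydrogenase
  metabolites:
    pyr_c: -1
    nadh_c: -1
    h_c: -1
    lac__L_c: 1
    nad_c: 1
  lower_bound: 0
  upper_bound: 1000.0
- id: L_LACt2r
  name: L-lactate proton symport
  metabolites:
    lac__L_e: -1
    h_e: -1
    lac__L_c: 1
    h_c: 1
  lower_bound: -1000.0
  upper_bound: 1000.0
- id: EX_lac__L_e
  name: L-lactate exchange
  metabolites:
    lac__L_e: -1
  lower_bound: 0
  upper_bound: 1000.0
remove: []
bound_changes: {}
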