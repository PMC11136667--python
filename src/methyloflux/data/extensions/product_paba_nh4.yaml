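name: product_paba_nh4
metabolites:
- id: 4abz_c
  name: 4-aminobenzoate
  compartment: c
  formula: C7H6NO2
  charge: -1
- id: 4abz_e
  name: 4-aminobenzoate
  compartment: e
  formula: C7H6NO2
  charge: -1
add:
- id: PABS
  name: 4-aminobenzoate synthesis (chorismate pathway lump, ammonium donor)
  metabolites:
    e4p_c: -1
    pep_c: -2
    atp_c: -1
    nadph_c: -1
    nh4_c: -1
    4abz_c: 1
    pyr_c: 1
    adp_c: 1
    nadp_c: 1
    pi_c: 4
    h2o_c: 1
    h_c: 1
  lower_bound: 0
  upper_bound: 1000.0
- id: PABAt
  name: 4-aminobenzoate export
  metabolites:
    4abz_c: -1
    4abz_e: 1
  lower_bound: 0
  upper_bound: 1000.0
- id: EX_4abz_e
  name: 4-aminobenzoate exchange
  metabolites:
    4abz_e: -1
  lower_bound: 0
  upper_bound: 1000.0
remove: []
bound_changes: {}
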