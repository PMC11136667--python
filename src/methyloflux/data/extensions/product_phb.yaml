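name: product_phb
metabolites:
- id: phb_c
  name: PHB monomer (3-hydroxybutanoate unit)
  compartment: c
  formula: C4H6O2
  charge: 0
add:
- id: PHB_SYN
  name: PHB monomer synthesis (phaCAB lump)
  metabolites:
    accoa_c: -2
    nadph_c: -1
    h_c: -1
    phb_c: 1
    coa_c: 2
    nadp_c: 1
  lower_bound: 0
  upper_bound: 1000.0
- id: DM_phb_c
  name: PHB monomer demand
  metabolites:
    phb_c: -1
  lower_bound: 0
  upper_bound: 1000.0
remove: []
bound_changes: {}
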