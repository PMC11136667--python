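name: rump_base
metabolites:
- id: meoh_c
  name: Methanol
  compartment: c
  formula: CH4O
  charge: 0
- id: meoh_e
  name: Methanol
  compartment: e
  formula: CH4O
  charge: 0
- id: fald_c
  name: Formaldehyde
  compartment: c
  formula: CH2O
  charge: 0
- id: h6p_c
  name: D-arabino-3-hexulose 6-phosphate
  compartment: c
  formula: C6H11O9P
  charge: -2
- id: s17bp_c
  name: Sedoheptulose 1,7-bisphosphate
  compartment: c
  formula: C7H12O13P2
  charge: -4
- id: 2ddg6p_c
  name: 2-dehydro-3-deoxy-D-gluconate 6-phosphate
  compartment: c
  formula: C6H8O9P
  charge: -3
add:
- id: MEDH
  name: methanol dehydrogenase (NAD)
  metabolites:
    meoh_c: -1
    nad_c: -1
    fald_c: 1
    nadh_c: 1
    h_c: 1
  lower_bound: 0
  upper_bound: 1000.0
- id: HPS
  name: 3-hexulose-6-phosphate synthase
  metabolites:
    fald_c: -1
    ru5p__D_c: -1
    h6p_c: 1
  lower_bound: 0
  upper_bound: 1000.0
- id: PHI
  name: 6-phospho-3-hexuloisomerase
  metabolites:
    h6p_c: -1
    f6p_c: 1
  lower_bound: 0
  upper_bound: 1000.0
- id: FALDDH
  name: formaldehyde dehydrogenase (lumped, glutathione-independent)
  metabolites:
    fald_c: -1
    nad_c: -1
    h2o_c: -1
    for_c: 1
    nadh_c: 1
    h_c: 2
  lower_bound: 0
  upper_bound: 1000.0
- id: FDH
  name: formate dehydrogenase (NAD)
  metabolites:
    for_c: -1
    nad_c: -1
    co2_c: 1
    nadh_c: 1
  lower_bound: 0
  upper_bound: 1000.0
- id: MEOHt
  name: methanol diffusion
  metabolites:
    meoh_e: -1
    meoh_c: 1
  lower_bound: -1000.0
  upper_bound: 1000.0
- id: EX_meoh_e
  name: methanol exchange
  metabolites:
    meoh_e: -1
  lower_bound: -60.0
  upper_bound: 1000.0
- id: FBA3
  name: sedoheptulose-1,7-bisphosphate aldolase
  metabolites:
    dhap_c: -1
    e4p_c: -1
    s17bp_c: 1
  lower_bound: -1000.0
  upper_bound: 1000.0
- id: SBP17BPase
  name: sedoheptulose-1,7-bisphosphatase
  metabolites:
    s17bp_c: -1
    h2o_c: -1
    s7p_c: 1
    pi_c: 1
  lower_bound: 0
  upper_bound: 1000.0
- id: EDD
  name: 6-phosphogluconate dehydratase
  metabolites:
    6pgc_c: -1
    2ddg6p_c: 1
    h2o_c: 1
  lower_bound: 0
  upper_bound: 1000.0
- id: EDA
  name: 2-dehydro-3-deoxy-phosphogluconate aldolase
  metabolites:
    2ddg6p_c: -1
    g3p_c: 1
    pyr_c: 1
  lower_bound: 0
  upper_bound: 1000.0
remove:
- ME1
- ME2
bound_changes:
  EX_glc__D_e:
  - 0.0
  - 1000.0
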