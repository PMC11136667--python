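name: c1_salvage
metabolites: []
add: []
remove: []
bound_changes:
  FALDDH:
  - -1000.0
  - 1000.0
  FDH:
  - -1000.0
  - 1000.0
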