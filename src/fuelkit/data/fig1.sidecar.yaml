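externals: []
functions:
  GO:0015144:
    bearer: putative glucose uptake protein
    input:
      bindings:
        operand: CHEBI:16646
      template: '{operand} is on one side of the membrane'
    operand: CHEBI:16646
    output:
      bindings:
        operand: CHEBI:16646
      template: '{operand} is on the other side of the membrane'
    process: GO:0034219
modes: {}
participants:
  CHEBI:16646:
    label: carbohydrate
    parents: []
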