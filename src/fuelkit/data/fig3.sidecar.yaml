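externals: []
functions:
  GO:0008324:
    input:
      bindings:
        operand: FX:cation
      template: '{operand} is on one side of the membrane'
    operand: FX:cation
    output:
      bindings:
        operand: FX:cation
      template: '{operand} is on the other side of the membrane'
  GO:0015075:
    input:
      bindings:
        operand: FX:ion
      template: '{operand} is on one side of the membrane'
    operand: FX:ion
    output:
      bindings:
        operand: FX:ion
      template: '{operand} is on the other side of the membrane'
modes: {}
participants:
  FX:cation:
    label: cation
    parents:
    - FX:ion
  FX:ion:
    label: ion
    parents: []
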