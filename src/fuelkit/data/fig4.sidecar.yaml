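externals: []
functions:
  GO:0022804:
    input:
      bindings:
        operand: FX:substance
      template: '{operand} is on one side of the membrane'
    mode: FX:active-transport-mode
    operand: FX:substance
    output:
      bindings:
        operand: FX:substance
      template: '{operand} is on the other side of the membrane'
  GO:0022857:
    input:
      bindings:
        operand: FX:substance
      template: '{operand} is on one side of the membrane'
    operand: FX:substance
    output:
      bindings:
        operand: FX:substance
      template: '{operand} is on the other side of the membrane'
modes:
  FX:active-transport-mode:
    description: the transporter binding the solute undergoes a series of conformational
      changes
participants:
  FX:substance:
    label: a substance
    parents: []
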