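externals: []
functions:
  GO:0005402:
    doer: FX:transporter-protein
    input:
      bindings:
        operand: FX:cation
      template: '{operand} is on one side of the membrane'
    mode: FX:symport-mode
    operand: FX:cation
    output:
      bindings:
        operand: FX:cation
      template: '{operand} is on the other side of the membrane'
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
  GO:0015144:
    input:
      bindings:
        operand: FX:carbohydrate
      template: '{operand} is on one side of the membrane'
    operand: FX:carbohydrate
    output:
      bindings:
        operand: FX:carbohydrate
      template: '{operand} is on the other side of the membrane'
    process: GO:0034219
  GO:0015238:
    input:
      bindings:
        operand: FX:drug
      template: '{operand} is on one side of the membrane'
    operand: FX:drug
    output:
      bindings:
        operand: FX:drug
      template: '{operand} is on the other side of the membrane'
  GO:0015291:
    input:
      bindings:
        operand: FX:specific-substance
      template: '{operand} is on one side of the membrane'
    mode: FX:secondary-active-transport-mode
    operand: FX:specific-substance
    output:
      bindings:
        operand: FX:specific-substance
      template: '{operand} is on the other side of the membrane'
  GO:0022804:
    input:
      bindings:
        operand: FX:specific-substance
      template: '{operand} is on one side of the membrane'
    mode: FX:active-transport-mode
    operand: FX:specific-substance
    output:
      bindings:
        operand: FX:specific-substance
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
  GO:0022891:
    input:
      bindings:
        operand: FX:specific-substance
      template: '{operand} is on one side of the membrane'
    operand: FX:specific-substance
    output:
      bindings:
        operand: FX:specific-substance
      template: '{operand} is on the other side of the membrane'
  GO:0090482:
    input:
      bindings:
        operand: FX:vitamin
      template: '{operand} is on one side of the membrane'
    operand: FX:vitamin
    output:
      bindings:
        operand: FX:vitamin
      template: '{operand} is on the other side of the membrane'
modes:
  FX:active-transport-mode:
    description: the transporter binding the solute undergoes a series of conformational
      changes
  FX:secondary-active-transport-mode:
    description: the transporter binds the solute and undergoes a series of conformational
      changes driven by chemiosmotic energy sources, including uniport, symport or
      antiport
    specializes: FX:active-transport-mode
  FX:symport-mode:
    description: the transporter co-transports the solute together with a coupled
      ion in the same direction
    specializes: FX:secondary-active-transport-mode
participants:
  FX:carbohydrate:
    label: carbohydrate
    parents:
    - FX:specific-substance
  FX:cation:
    label: cation
    parents:
    - FX:ion
  FX:drug:
    label: drug
    parents:
    - FX:specific-substance
  FX:ion:
    label: ion
    parents:
    - FX:specific-substance
  FX:solute:
    label: solute
    parents:
    - FX:specific-substance
  FX:specific-substance:
    label: a specific substance or group of substances
    parents:
    - FX:substance
  FX:substance:
    label: a substance
    parents: []
  FX:sugar:
    label: sugar
    parents:
    - FX:carbohydrate
  FX:transporter-protein:
    label: transporter protein
    parents: []
  FX:vitamin:
    label: vitamin
    parents:
    - FX:specific-substance
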