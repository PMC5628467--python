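externals: []
functions:
  FX:0000001:
    input:
      bindings:
        operand: FX:apolipoprotein
      template: '{operand} is available to the receptor'
    operand: FX:apolipoprotein
    output:
      bindings:
        operand: FX:apolipoprotein
      template: binding of {operand} is transduced into a cellular response
  FX:0000002:
    input:
      bindings:
        operand: FX:cargo
      template: '{operand} is available to the receptor'
    mode: FX:cargo-uptake-mode
    operand: FX:cargo
    output:
      bindings:
        operand: FX:cargo
      template: binding of {operand} is transduced into a cellular response
  FX:0000003:
    input:
      bindings:
        operand: FX:molecular-pattern
      template: '{operand} is available to the receptor'
    operand: FX:molecular-pattern
    output:
      bindings:
        operand: FX:molecular-pattern
      template: binding of {operand} is transduced into a cellular response
  FX:0000004:
    input:
      bindings:
        operand: FX:virus
      template: '{operand} is available to the receptor'
    operand: FX:virus
    output:
      bindings:
        operand: FX:virus
      template: binding of {operand} is transduced into a cellular response
  GO:0004872:
    input:
      bindings:
        operand: FX:ligand
      template: '{operand} is available to the receptor'
    operand: FX:ligand
    output:
      bindings:
        operand: FX:ligand
      template: binding of {operand} is transduced into a cellular response
  GO:0005055:
    input:
      bindings:
        operand: FX:laminin
      template: '{operand} is available to the receptor'
    operand: FX:laminin
    output:
      bindings:
        operand: FX:laminin
      template: binding of {operand} is transduced into a cellular response
  GO:0038023:
    input:
      bindings:
        operand: FX:signal
      template: '{operand} is available to the receptor'
    operand: FX:signal
    output:
      bindings:
        operand: FX:signal
      template: binding of {operand} is transduced into a cellular response
  GO:0099600:
    input:
      bindings:
        operand: FX:extracellular-or-intracellular-signal
      template: '{operand} is available to the receptor'
    operand: FX:extracellular-or-intracellular-signal
    output:
      bindings:
        operand: FX:extracellular-or-intracellular-signal
      template: binding of {operand} is transduced into a cellular response
modes:
  FX:cargo-uptake-mode:
    description: binds a cargo macromolecule and delivers it for internalization by
      endocytosis
participants:
  FX:apolipoprotein:
    label: apolipoprotein
    parents:
    - FX:ligand
  FX:cargo:
    label: cargo macromolecule
    parents:
    - FX:ligand
  FX:extracellular-or-intracellular-signal:
    label: extracellular or intracellular signal
    parents:
    - FX:signal
  FX:laminin:
    label: laminin
    parents:
    - FX:ligand
  FX:ligand:
    label: ligand or signal
    parents: []
  FX:molecular-pattern:
    label: molecular pattern
    parents:
    - FX:ligand
  FX:signal:
    label: signal
    parents:
    - FX:ligand
  FX:virus:
    label: virus particle
    parents:
    - FX:ligand
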