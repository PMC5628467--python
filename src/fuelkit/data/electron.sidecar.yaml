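externals: []
functions:
  GO:0009055:
    input:
      bindings:
        operand: FX:electron
      template: '{operand} is held by the donor'
    operand: FX:electron
    output:
      bindings:
        operand: FX:electron
      template: '{operand} is held by the acceptor'
  GO:0045154:
    input:
      bindings:
        operand: FX:electron
      template: '{operand} is held by the donor'
    mode: FX:cco-mode
    operand: FX:electron
    output:
      bindings:
        operand: FX:electron
      template: '{operand} is held by the acceptor'
  GO:0045156:
    input:
      bindings:
        operand: FX:electron
      template: '{operand} is held by the donor'
    mode: FX:cyclic-mode
    operand: FX:electron
    output:
      bindings:
        operand: FX:electron
      template: '{operand} is held by the acceptor'
modes:
  FX:cco-mode:
    description: transfers electrons within the cytochrome c oxidase complex
  FX:cyclic-mode:
    description: transfers electrons within the cyclic electron transport pathway
      of photosynthesis
participants:
  FX:electron:
    label: electron
    parents: []
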