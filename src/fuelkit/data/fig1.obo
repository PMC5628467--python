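format-version: 1.2

[Term]
id: GO:0015144
name: carbohydrate transmembrane transporter activity
def: "Catalysis of the transfer of carbohydrate from one side of the membrane to the other." []
synonym: sugar transporter
relationship: part_of GO:0034219
relationship: transports_or_maintains_localization_of CHEBI:16646

[Term]
id: GO:0034219
name: carbohydrate transmembrane transport
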