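format-version: 1.2

[Term]
id: GO:0005402
name: cation:sugar symporter activity
is_a: GO:0008324
is_a: GO:0015291

[Term]
id: GO:0008324
name: cation transmembrane transporter activity
is_a: GO:0015075

[Term]
id: GO:0015075
name: ion transmembrane transporter activity
is_a: GO:0022891

[Term]
id: GO:0015144
name: carbohydrate transmembrane transporter activity
def: "Catalysis of the transfer of carbohydrate from one side of the membrane to the other." []
synonym: sugar transporter
is_a: GO:0022891
relationship: part_of GO:0034219

[Term]
id: GO:0015238
name: drug transmembrane transporter activity
is_a: GO:0022857

[Term]
id: GO:0015291
name: secondary active transmembrane transporter activity
is_a: GO:0022804

[Term]
id: GO:0022804
name: active transmembrane transporter activity
is_a: GO:0022857

[Term]
id: GO:0022857
name: transmembrane transporter activity

[Term]
id: GO:0022891
name: substrate-specific transmembrane transporter activity
is_a: GO:0022857

[Term]
id: GO:0090482
name: vitamin transmembrane transporter activity
is_a: GO:0022857

[Term]
id: GO:0034219
name: carbohydrate transmembrane transport
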