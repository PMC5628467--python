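format-version: 1.2

[Term]
id: GO:0008324
name: cation transmembrane transporter activity
is_a: GO:0015075

[Term]
id: GO:0015075
name: ion transmembrane transporter activity
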