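format-version: 1.2

[Term]
id: FX:0000001
name: apolipoprotein receptor activity
is_a: GO:0004872

[Term]
id: FX:0000002
name: cargo receptor activity
is_a: GO:0004872

[Term]
id: FX:0000003
name: pattern recognition receptor activity
is_a: GO:0004872

[Term]
id: FX:0000004
name: virus receptor activity
is_a: GO:0004872

[Term]
id: GO:0004872
name: receptor activity

[Term]
id: GO:0005055
name: laminin receptor activity
is_a: GO:0004872

[Term]
id: GO:0038023
name: signaling receptor activity
is_a: GO:0004872

[Term]
id: GO:0099600
name: transmembrane receptor activity
is_a: GO:0004872
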