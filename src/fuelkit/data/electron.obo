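format-version: 1.2

[Term]
id: GO:0009055
name: electron carrier activity

[Term]
id: GO:0045154
name: electron transporter, transferring electrons within cytochrome c oxidase complex activity
is_a: GO:0009055

[Term]
id: GO:0045156
name: electron transporter, transferring electrons within the cyclic electron transport pathway of photosynthesis activity
is_a: GO:0009055
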