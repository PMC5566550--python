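compound,residue,C1,C2,C3,C4,C5,C6
1,Manp_glycosylating,98.2,72.6,72.1,68.6,75.9,62.9
1,Manp_OMe,102.6,71.2,78.8,67.9,74.6,63.1
2,Manp_glycosylating,98.5,72.5,72.1,68.5,75.9,63.0
2,Manp_OMe,102.5,71.9,72.3,73.6,73.4,62.6
3,Manp_glycosylating,97.7,72.2,71.7,68.3,75.5,62.7
3,Manp_OMe,102.5,71.8,72.2,68.0,73.2,66.0
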