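compound,residue,H1,H2,H3,H4,H5,H6a,H6b
1,Manp_glycosylating,5.54,3.93,3.81,3.64,3.84,3.86,3.75
1,Manp_OMe,4.69,4.06,4.34,3.82,3.57,3.89,3.72
2,Manp_glycosylating,5.54,3.96,3.82,3.68,3.82,3.87,3.75
2,Manp_OMe,4.68,3.84,3.88,4.30,3.57,3.85,3.83
3,Manp_glycosylating,5.49,3.94,3.83,3.63,3.83,3.83,3.71
3,Manp_OMe,4.65,3.79,3.68,3.72,3.58,4.16,4.12
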