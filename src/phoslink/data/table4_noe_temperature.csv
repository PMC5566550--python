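compound,pair,temperature_K,relative_noe
1,H1'-H3,283,0.13
1,H1'-H3,303,0.14
1,H1'-H3,323,0.14
1,H1'-H2,283,0.11
1,H1'-H2,303,0.09
1,H1'-H2,323,0.09
2,H1'-H4,283,0.18
2,H1'-H4,303,0.18
2,H1'-H4,323,0.18
2,H1'-H6ab,283,0.24
2,H1'-H6ab,303,0.24
2,H1'-H6ab,323,0.33
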