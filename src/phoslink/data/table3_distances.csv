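compound,pair,distance_A
1,H1'-H3,3.5
1,H1'-H2,3.3
2,H1'-H4,3.1
2,H1'-H6a,3.6
2,H1'-H6b,3.6
3,H1'-H6a,4.8
3,H1'-H6b,4.7
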