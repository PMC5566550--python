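compound,pair,experimental_Hz,qualifier,calculated_Hz
1,P-H1',7.6,,8.8
1,P-H3,8.0,,8.9
2,P-H1',7.3,,8.1
2,P-H4,9.0,,9.5
3,P-H1',7.7,,8.8
3,P-H6a,5.9,,6.8
3,P-H6b,6.8,,8.0
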